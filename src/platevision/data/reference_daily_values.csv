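# Daily reference amounts used to convert percent-daily-value nutrition
# figures to absolute amounts. Adults >70 y, sex-averaged where male/female
# requirements differ; macronutrients follow the 2000-kcal label convention.
# EDITABLE STAND-IN VALUES, not an authoritative regulatory table: replace
# this file with your jurisdiction's reference table for production use.
nutrient,amount,unit
calories,2000,kcal
carbohydrates,300,g
fats,65,g
fiber,25,g
protein,50,g
calcium,1200,mg
iron,8,mg
sodium,1200,mg
vitamin_b6,1.6,mg
vitamin_c,82.5,mg
vitamin_d,15,ug
vitamin_k,105,ug
zinc,9.5,mg
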