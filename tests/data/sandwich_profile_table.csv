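nutrient,sandwich_0,sandwich_1,sandwich_2,sandwich_3,sandwich_4,sandwich_5
energy,561,437,457,413,433,264
carbohydrate,35,28,34,26,33,30
protein,34,32,30,39,37,13
total_fat,28,22,22,16,16,10
saturated_fat,9.6,10.3,10.3,8.6,8.6,3.8
dietary_fiber,2.1,4.1,1.9,4.0,1.8,4.1
iron,4.7,3.1,3.8,2.0,2.8,2.4
calcium,251.2,409.7,455.2,412.7,458.2,135.8
magnesium,45.4,79.2,48.6,86.9,56.3,35.7
potassium,485,544.9,471.4,521.0,447.6,324.1
sodium,1393,1298.3,1387.5,777.0,866.2,681.8
folate_dfe,111,54.9,129.2,47.5,121.9,98.3
niacin,7.9,6.6,6.8,10.6,10.8,3.2
riboflavin,0.5,0.45,0.51,0.34,0.40,0.18
thiamin,0.4,0.39,0.48,0.28,0.37,0.25
vitamin_a_rae,60.1,143.1,143.1,140.5,140.5,38.8
vitamin_c,3.6,4.5,4.5,4.9,4.9,2.4
vitamin_d,0.5,0.93,0.93,0.30,0.30,0.08
vitamin_e_at,0.8,1.16,0.76,1.08,0.68,0.78
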