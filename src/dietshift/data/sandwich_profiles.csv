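name,groups_known,energy,carbohydrate,protein,total_fat,saturated_fat,dietary_fiber,iron,calcium,magnesium,potassium,sodium,folate_dfe,niacin,riboflavin,thiamin,vitamin_a_rae,vitamin_c,vitamin_d,vitamin_e_at,added_sugar,fg_total_fruit,fg_whole_fruit,fg_total_veg,fg_greens_beans,fg_whole_grains,fg_refined_grains,fg_dairy,fg_total_protein,fg_seafood_plant_protein,fg_mufa,fg_pufa,fg_sfa,fg_added_sugar,fg_solid_fat_kcal,fg_alcohol
Sandwich 0,0,561,35,34,28,9.6,2.1,4.7,251.2,45.4,485,1393,111,7.9,0.5,0.4,60.1,3.6,0.5,0.8,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Sandwich 1,1,437,28,32,22,10.3,4.1,3.1,409.7,79.2,544.9,1298.3,54.9,6.6,0.45,0.39,143.1,4.5,0.93,1.16,0,0,0,0.2,0.1,2.0,0,1.0,2.5,0,7.8,3.9,10.3,0,92.7,0
Sandwich 2,1,457,34,30,22,10.3,1.9,3.8,455.2,48.6,471.4,1387.5,129.2,6.8,0.51,0.48,143.1,4.5,0.93,0.76,0,0,0,0.2,0.1,0,2.0,1.0,2.5,0,7.8,3.9,10.3,0,92.7,0
Sandwich 3,1,413,26,39,16,8.6,4.0,2.0,412.7,86.9,521.0,777.0,47.5,10.6,0.34,0.28,140.5,4.9,0.30,1.08,0,0,0,0.2,0.1,2.0,0,1.0,2.5,0,4.9333,2.4667,8.6,0,77.4,0
Sandwich 4,1,433,33,37,16,8.6,1.8,2.8,458.2,56.3,447.6,866.2,121.9,10.8,0.40,0.37,140.5,4.9,0.30,0.68,0,0,0,0.2,0.1,0,2.0,1.0,2.5,0,4.9333,2.4667,8.6,0,77.4,0
Sandwich 5,1,264,30,13,10,3.8,4.1,2.4,135.8,35.7,324.1,681.8,98.3,3.2,0.18,0.25,38.8,2.4,0.08,0.78,0,0,0,0.1,0,1.0,0,0.5,1.5,0,4.1333,2.0667,3.8,0,34.2,0
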