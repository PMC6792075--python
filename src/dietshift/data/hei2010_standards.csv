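name,max_points,basis,value_at_zero,value_at_max,direction
total_fruit,5,density,0.0,0.8,adequacy
whole_fruit,5,density,0.0,0.4,adequacy
total_veg,5,density,0.0,1.1,adequacy
greens_beans,5,density,0.0,0.2,adequacy
whole_grains,10,density,0.0,1.5,adequacy
dairy,10,density,0.0,1.3,adequacy
total_protein,5,density,0.0,2.5,adequacy
seafood_plant_protein,5,density,0.0,0.8,adequacy
fatty_acids,10,ratio,1.2,2.5,adequacy
refined_grains,10,density,4.3,1.8,moderation
sodium,10,density,2.0,1.1,moderation
empty_calories,20,percent_energy,50.0,19.0,moderation
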