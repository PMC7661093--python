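# name: pathway
# kind: closed-set
# source: https://www.cbd.int/doc/meetings/sbstta/sbstta-18/official/sbstta-18-09-add1-en.pdf
# version: CBD 2014 pathway classification, level-1_level-2 codes (replaceable data file)
cbd_2014_pathway:release
cbd_2014_pathway:release_biological_control
cbd_2014_pathway:release_erosion_control
cbd_2014_pathway:release_fishery
cbd_2014_pathway:release_hunting
cbd_2014_pathway:release_landscape_improvement
cbd_2014_pathway:release_conservation
cbd_2014_pathway:release_other
cbd_2014_pathway:escape
cbd_2014_pathway:escape_agriculture
cbd_2014_pathway:escape_aquaculture
cbd_2014_pathway:escape_zoo
cbd_2014_pathway:escape_pet
cbd_2014_pathway:escape_farm
cbd_2014_pathway:escape_forestry
cbd_2014_pathway:escape_fur_farm
cbd_2014_pathway:escape_horticulture
cbd_2014_pathway:escape_ornamental
cbd_2014_pathway:escape_research
cbd_2014_pathway:escape_food_bait
cbd_2014_pathway:escape_other
cbd_2014_pathway:contaminant
cbd_2014_pathway:contaminant_nursery
cbd_2014_pathway:contaminant_bait
cbd_2014_pathway:contaminant_food
cbd_2014_pathway:contaminant_on_animals
cbd_2014_pathway:contaminant_on_animals_parasite
cbd_2014_pathway:contaminant_on_plants
cbd_2014_pathway:contaminant_plant_parasite
cbd_2014_pathway:contaminant_seed
cbd_2014_pathway:contaminant_timber
cbd_2014_pathway:contaminant_habitat_material
cbd_2014_pathway:stowaway
cbd_2014_pathway:stowaway_fishing_equipment
cbd_2014_pathway:stowaway_ballast_water
cbd_2014_pathway:stowaway_hull_fouling
cbd_2014_pathway:stowaway_container
cbd_2014_pathway:stowaway_airplane
cbd_2014_pathway:stowaway_ship
cbd_2014_pathway:stowaway_machinery
cbd_2014_pathway:stowaway_people
cbd_2014_pathway:stowaway_packing_material
cbd_2014_pathway:stowaway_vehicles
cbd_2014_pathway:stowaway_other
cbd_2014_pathway:corridor
cbd_2014_pathway:corridor_water
cbd_2014_pathway:corridor_land
cbd_2014_pathway:unaided
cbd_2014_pathway:natural_dispersal
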