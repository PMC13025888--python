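type_name,age_group,p50_g_day,p95_g_day
Solanaceous Vegetables,le6,50,120
Solanaceous Vegetables,7_12,60,150
Solanaceous Vegetables,13_17,80,150
Solanaceous Vegetables,18_59,96,180
Solanaceous Vegetables,ge60,100,200
Cruciferous Vegetables,le6,50,50
Cruciferous Vegetables,7_12,80,130
Cruciferous Vegetables,13_17,100,150
Cruciferous Vegetables,18_59,200,200
Cruciferous Vegetables,ge60,105,200
Cucurbit Vegetables,le6,50,131.7
Cucurbit Vegetables,7_12,60,150
Cucurbit Vegetables,13_17,80,174.4
Cucurbit Vegetables,18_59,100,200
Cucurbit Vegetables,ge60,100,200
Tuber and Root Vegetables,le6,43.5,100
Tuber and Root Vegetables,7_12,60,150
Tuber and Root Vegetables,13_17,79,148
Tuber and Root Vegetables,18_59,100,200
Tuber and Root Vegetables,ge60,100,200
Aquatic Vegetables,le6,35,101
Aquatic Vegetables,7_12,50,140
Aquatic Vegetables,13_17,77.5,146.5
Aquatic Vegetables,18_59,80,160
Aquatic Vegetables,ge60,82,181.2
Leafy Vegetables,le6,50,120
Leafy Vegetables,7_12,80,150
Leafy Vegetables,13_17,100,180
Leafy Vegetables,18_59,100,200
Leafy Vegetables,ge60,100,200
Green Tea,le6,0,0
Green Tea,7_12,1,1
Green Tea,13_17,3,5.25
Green Tea,18_59,3,10
Green Tea,ge60,4,11.75
Black Tea,le6,0,0
Black Tea,7_12,3,3
Black Tea,13_17,3,3
Black Tea,18_59,3,7.45
Black Tea,ge60,2,6.1
Oolong Tea,le6,0,0
Oolong Tea,7_12,0,0
Oolong Tea,13_17,0,0
Oolong Tea,18_59,3,10
Oolong Tea,ge60,6,6
Dark Tea,le6,0,0
Dark Tea,7_12,0,0
Dark Tea,13_17,0,0
Dark Tea,18_59,3,1.5
Dark Tea,ge60,5,2
Fish,le6,50,100
Fish,7_12,50,150
Fish,13_17,70,150
Fish,18_59,80,200
Fish,ge60,70,200
Crustaceans,le6,50,120
Crustaceans,7_12,50,150
Crustaceans,13_17,60,200
Crustaceans,18_59,60,175
Crustaceans,ge60,52,150
Mollusks,le6,60,400
Mollusks,7_12,60,350
Mollusks,13_17,80,400
Mollusks,18_59,80,500
Mollusks,ge60,70,500
Citrus Fruits,le6,80,180
Citrus Fruits,7_12,100,180
Citrus Fruits,13_17,106,200
Citrus Fruits,18_59,110,200
Citrus Fruits,ge60,200,200
Melons and Gourd Fruits,le6,120,250
Melons and Gourd Fruits,7_12,140,300
Melons and Gourd Fruits,13_17,180,250
Melons and Gourd Fruits,18_59,180,380
Melons and Gourd Fruits,ge60,180,350
Stone Fruits,le6,100,230
Stone Fruits,7_12,123.5,240
Stone Fruits,13_17,150,250
Stone Fruits,18_59,150,258
Stone Fruits,ge60,150,258
Berries and Other Small Fruits,le6,80,200
Berries and Other Small Fruits,7_12,100,200
Berries and Other Small Fruits,13_17,100,200
Berries and Other Small Fruits,18_59,100,240
Berries and Other Small Fruits,ge60,105,250
Tropical and Subtropical Fruits,le6,96,200
Tropical and Subtropical Fruits,7_12,100,216.5
Tropical and Subtropical Fruits,13_17,115,250
Tropical and Subtropical Fruits,18_59,120,250
Tropical and Subtropical Fruits,ge60,120,250
Pome Fruits,le6,120,225
Pome Fruits,7_12,148,240
Pome Fruits,13_17,160,250
Pome Fruits,18_59,160,258
Pome Fruits,ge60,155,258
Cereal-based Canned Foods,le6,0,0
Cereal-based Canned Foods,7_12,0,0
Cereal-based Canned Foods,13_17,300,300
Cereal-based Canned Foods,18_59,150,360
Cereal-based Canned Foods,ge60,355,465
Canned Vegetables and Vegetable Products,le6,0,0
Canned Vegetables and Vegetable Products,7_12,20,20
Canned Vegetables and Vegetable Products,13_17,0,0
Canned Vegetables and Vegetable Products,18_59,20,20
Canned Vegetables and Vegetable Products,ge60,15,19
Canned Fruits and Fruit Products,le6,0,0
Canned Fruits and Fruit Products,7_12,0,0
Canned Fruits and Fruit Products,13_17,0,0
Canned Fruits and Fruit Products,18_59,40,40
Canned Fruits and Fruit Products,ge60,0,0
Canned Meat and Meat Products,le6,10,66.7
Canned Meat and Meat Products,7_12,13.3,100
Canned Meat and Meat Products,13_17,20,123.3
Canned Meat and Meat Products,18_59,20,66.7
Canned Meat and Meat Products,ge60,13.3,66.7
Canned Aquatic Products,le6,16.65,93.3
Canned Aquatic Products,7_12,22.2,139.95
Canned Aquatic Products,13_17,33.3,186.7
Canned Aquatic Products,18_59,33.3,93.3
Canned Aquatic Products,ge60,22.2,93.3
Canned Edible Fungi and Fungal Product,le6,0,0
Canned Edible Fungi and Fungal Product,7_12,20,29
Canned Edible Fungi and Fungal Product,13_17,0,0
Canned Edible Fungi and Fungal Product,18_59,40,46
Canned Edible Fungi and Fungal Product,ge60,35,35
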