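category,type_name,n,n_detect,mean,p50,p95,iqr,min,max,lod
fresh_vegetables,Solanaceous Vegetables,32,11,0.04,0.00,0.27,0.01,0.00,0.34,0.004
fresh_vegetables,Cruciferous Vegetables,40,12,0.01,0.00,0.03,0.00,0.00,0.04,0.004
fresh_vegetables,Cucurbit Vegetables,24,4,0.01,0.00,0.04,0.00,0.00,0.04,0.004
fresh_vegetables,Tuber and Root Vegetables,239,72,0.06,0.00,0.33,0.01,0.00,4.53,0.004
fresh_vegetables,Aquatic Vegetables,199,64,0.01,0.01,0.04,0.01,0.00,0.10,0.004
fresh_vegetables,Leafy Vegetables,139,35,0.04,0.00,0.21,0.00,0.00,1.14,0.004
tea,Green Tea,268,204,0.08,0.03,0.37,0.08,0.00,1.30,0.008
tea,Black Tea,55,45,0.08,0.04,0.31,0.06,0.00,0.57,0.008
tea,Oolong Tea,31,25,0.13,0.03,0.31,0.09,0.00,2.02,0.008
tea,Dark Tea,24,23,0.08,0.03,0.49,0.03,0.00,0.57,0.008
fresh_aquatic,Fish,175,26,0.26,0.01,0.50,0.15,0.00,10.30,0.004
fresh_aquatic,Crustaceans,157,90,0.02,0.01,0.10,0.01,0.00,0.40,0.004
fresh_aquatic,Mollusks,60,26,0.01,0.00,0.03,0.00,0.00,0.50,0.004
fresh_fruits,Citrus Fruits,8,1,0.00,0.00,0.01,0.00,0.00,0.02,0.004
fresh_fruits,Melons and Gourd Fruits,9,3,0.01,0.00,0.02,0.00,0.00,0.02,0.004
fresh_fruits,Stone Fruits,19,7,0.00,0.00,0.01,0.00,0.00,0.02,0.004
fresh_fruits,Berries and Other Small Fruits,36,3,0.00,0.00,0.00,0.00,0.00,0.02,0.004
fresh_fruits,Tropical and Subtropical Fruits,38,6,0.00,0.00,0.01,0.00,0.00,0.03,0.004
fresh_fruits,Pome Fruits,23,9,0.02,0.00,0.03,0.01,0.00,0.24,0.004
canned,Cereal-based Canned Foods,52,27,0.04,0.01,0.21,0.04,0.00,0.37,0.004
canned,Canned Vegetables and Vegetable Products,57,38,1.05,0.12,5.13,0.23,0.00,19.80,0.004
canned,Canned Fruits and Fruit Products,82,65,12.67,0.15,80.73,5.79,0.00,134.00,0.004
canned,Canned Meat and Meat Products,71,47,0.96,0.03,3.42,0.10,0.00,23.70,0.004
canned,Canned Aquatic Products,93,62,0.12,0.02,0.62,0.10,0.00,1.51,0.004
canned,Canned Edible Fungi and Fungal Product,83,60,1.61,0.06,0.48,0.12,0.00,38.90,0.004
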