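food,position,trial,predicted_ml,ground_truth_ml
Chickpeas,1,1,77.58,100
Chickpeas,1,2,75.2526,100
Chickpeas,1,3,75.2526,100
Chickpeas,1,4,78.3558,100
Chickpeas,2,1,76.0284,100
Chickpeas,2,2,76.8042,100
Chickpeas,2,3,74.4768,100
Chickpeas,2,4,80.6832,100
Chickpeas,3,1,73.701,100
Chickpeas,3,2,74.4768,100
Chickpeas,3,3,73.701,100
Chickpeas,3,4,73.701,100
French Fries,1,1,147.54,180
French Fries,1,2,144.5892,180
French Fries,1,3,146.0646,180
French Fries,1,4,141.6384,180
French Fries,2,1,140.163,180
French Fries,2,2,151.9662,180
French Fries,2,3,144.5892,180
French Fries,2,4,147.54,180
French Fries,3,1,149.0154,180
French Fries,3,2,151.9662,180
French Fries,3,3,147.54,180
French Fries,3,4,146.0646,180
Popcorn,1,1,100.41,130
Popcorn,1,2,95.38,130
Popcorn,1,3,103.412,130
Popcorn,1,4,98.392,130
Popcorn,2,1,95.38,130
Popcorn,2,2,103.412,130
Popcorn,2,3,102.408,130
Popcorn,2,4,104.416,130
Popcorn,3,1,98.392,130
Popcorn,3,2,97.388,130
Popcorn,3,3,102.408,130
Popcorn,3,4,100.4,130
Chocolate Brownie,1,1,135.44,135
Chocolate Brownie,1,2,131.81,135
Chocolate Brownie,1,3,131.81,135
Chocolate Brownie,1,4,134.5,135
Chocolate Brownie,2,1,130.465,135
Chocolate Brownie,2,2,138.535,135
Chocolate Brownie,2,3,131.81,135
Chocolate Brownie,2,4,138.535,135
Chocolate Brownie,3,1,133.155,135
Chocolate Brownie,3,2,129.12,135
Chocolate Brownie,3,3,139.88,135
Chocolate Brownie,3,4,131.81,135
Banana,1,1,96.192,120
Banana,1,2,97.194,120
Banana,1,3,98.196,120
Banana,1,4,99.198,120
Banana,2,1,103.206,120
Banana,2,2,99.198,120
Banana,2,3,101.202,120
Banana,2,4,105.21,120
Banana,3,1,97.194,120
Banana,3,2,103.206,120
Banana,3,3,101.202,120
Banana,3,4,100.2,120
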