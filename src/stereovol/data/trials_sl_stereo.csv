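food,position,trial,predicted_ml,ground_truth_ml
Chickpeas,1,1,103.47,100
Chickpeas,1,2,96.27,100
Chickpeas,1,3,89.92,100
Chickpeas,1,4,88.84,100
Chickpeas,2,1,101.99,100
Chickpeas,2,2,100.24,100
Chickpeas,2,3,86.74,100
Chickpeas,2,4,91.87,100
Chickpeas,3,1,92.79,100
Chickpeas,3,2,94.23,100
Chickpeas,3,3,89.04,100
Chickpeas,3,4,89.82,100
French Fries,1,1,166.22,180
French Fries,1,2,164.76,180
French Fries,1,3,163.15,180
French Fries,1,4,165.40,180
French Fries,2,1,165.65,180
French Fries,2,2,164.85,180
French Fries,2,3,190.07,180
French Fries,2,4,166.98,180
French Fries,3,1,166.07,180
French Fries,3,2,180.80,180
French Fries,3,3,164.98,180
French Fries,3,4,177.18,180
Popcorn,1,1,134.61,130
Popcorn,1,2,123.65,130
Popcorn,1,3,127.80,130
Popcorn,1,4,137.74,130
Popcorn,2,1,137.98,130
Popcorn,2,2,149.75,130
Popcorn,2,3,143.44,130
Popcorn,2,4,150.04,130
Popcorn,3,1,142.30,130
Popcorn,3,2,136.61,130
Popcorn,3,3,127.67,130
Popcorn,3,4,138.83,130
Chocolate Brownie,1,1,141.29,135
Chocolate Brownie,1,2,137.32,135
Chocolate Brownie,1,3,142.12,135
Chocolate Brownie,1,4,136.03,135
Chocolate Brownie,2,1,148.91,135
Chocolate Brownie,2,2,152.29,135
Chocolate Brownie,2,3,143.86,135
Chocolate Brownie,2,4,149.20,135
Banana,1,1,108.86,120
Banana,1,2,118.38,120
Banana,1,3,130.28,120
Banana,1,4,117.82,120
Banana,2,1,126.28,120
Banana,2,2,118.29,120
Banana,2,3,125.67,120
Banana,2,4,124.72,120
Banana,3,1,102.03,120
Banana,3,2,103.44,120
Banana,3,3,101.94,120
Banana,3,4,109.28,120
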