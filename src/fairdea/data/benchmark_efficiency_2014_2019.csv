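# Published benchmark: comprehensive (CRS) efficiency of healthcare resource
# allocation for 31 Chinese provinces/municipalities, 2014-2019, as printed
# in the provincial study this package's report layouts follow.
province,y2014,y2015,y2016,y2017,y2018,y2019
Beijing,0.925,0.95,0.995,0.95,0.988,1
Tianjin,1,1,0.996,0.973,0.994,1
Hebei,1,1,1,1,1,0.95
Shanxi,0.599,0.60,0.659,0.675,0.703,0.676
Inner Mongolia,0.645,0.64,0.67,0.69,0.711,0.665
Liaoning,0.703,0.71,0.731,0.728,0.73,0.726
Jilin,0.676,0.69,0.71,0.731,0.715,0.716
Heilongjiang,0.69,0.74,0.783,0.793,0.772,0.829
Shanghai,1,1,1,1,1,1
Jiangsu,0.91,0.93,0.923,0.939,0.904,0.896
Zhejiang,1,1,1,1,1,1
Anhui,0.908,0.91,0.915,0.936,0.94,0.931
Fujian,0.892,0.88,0.912,0.904,0.903,0.898
Jiangxi,1,1,1,1,1,1
Shandong,0.892,0.89,0.907,0.917,0.895,0.884
Henan,1,1,1,1,1,1
Hubei,0.962,0.95,0.94,0.964,0.978,1
Hunan,0.974,1,1,1,1,0.989
Guangdong,1,1,1,1,1,0.998
Guangxi,1,1,1,1,1,1
Hainan,0.923,0.93,0.95,0.961,0.957,0.938
Chongqing,0.996,1,1,1,0.972,1
Sichuan,0.984,1,1,1,0.995,1
Guizhou,1,1,1,1,1,1
Yunnan,1,1,1,1,1,1
Tibet,1,1,1,1,1,1
Shaanxi,0.809,0.84,0.843,0.861,0.883,0.839
Gansu,0.894,0.93,1,0.966,1,0.973
Qinghai,0.902,0.85,0.923,0.882,0.944,0.997
Ningxia,0.931,0.95,0.969,0.966,1,1
Xinjiang,0.932,0.98,0.992,0.971,0.957,1
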