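# Published benchmark: per-province Malmquist total factor productivity
# decomposition (geometric means over 2014-2019 adjacent-year pairs) for
# 31 Chinese provinces/municipalities.  Column order as printed:
# effch, techch, sech, pech, tfpch.  Spellings normalized (the printed
# western-region "Shanxi" row is Shaanxi).
province,effch,techch,sech,pech,tfpch,rank
Beijing,1.016,0.986,1.014,1.002,1.002,1
Tianjin,1,0.968,1,1,0.968,15
Hebei,0.99,0.956,0.99,1,0.946,27
Liaoning,1.006,0.969,1.008,0.999,0.975,11
Shanghai,1,0.977,1,1,0.977,8
Jiangsu,0.997,0.979,0.996,1.001,0.976,9
Zhejiang,1,0.974,1,1,0.974,13
Fujian,1.002,0.973,1.002,1,0.975,11
Shandong,0.998,0.958,0.989,1.009,0.956,23
Guangdong,1,0.968,1,1,0.967,16
Hainan,1.003,0.94,0.992,1.011,0.943,28
Shanxi,1.025,0.938,1.025,1,0.961,22
Jilin,1.012,0.973,1.012,0.999,0.984,4
Heilongjiang,1.037,0.958,1.038,0.999,0.993,3
Anhui,1.005,0.977,1.003,1.002,0.981,6
Jiangxi,1,0.962,1,1,0.962,21
Henan,1,0.939,1,1,0.939,29
Hubei,1.008,0.964,1,1.008,0.971,14
Hunan,1.003,0.949,1,1.003,0.952,25
Guangxi,1,0.947,1,1,0.947,26
Inner Mongolia,1.006,0.97,1.006,1,0.976,9
Chongqing,1.001,0.977,1,1.001,0.978,7
Sichuan,1.003,0.964,1,1.003,0.967,16
Guizhou,1,0.937,1,1,0.937,30
Yunnan,1,0.964,1,1,0.964,20
Tibet,1,0.888,1,1,0.888,31
Shaanxi,1.007,0.988,1.008,0.999,0.995,2
Gansu,1.017,0.951,1.012,1.005,0.967,16
Qinghai,1.02,0.938,1.005,1.015,0.956,23
Ningxia,1.014,0.953,1,1.014,0.967,16
Xinjiang,1.014,0.969,1.011,1.003,0.983,5
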