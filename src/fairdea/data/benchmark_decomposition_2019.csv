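# Published benchmark: 2019 comprehensive efficiency (te), pure technical
# efficiency (pte), scale efficiency (se) and returns-to-scale label for
# 31 Chinese provinces/municipalities ("-" = constant returns).
province,te,pte,se,rts
Beijing,1,1,1,-
Tianjin,1,1,1,-
Hebei,0.95,0.95,0.999,drs
Shanxi,0.676,0.676,1,-
Inner Mongolia,0.665,0.666,0.999,irs
Liaoning,0.726,0.731,0.994,irs
Jilin,0.716,0.719,0.997,drs
Heilongjiang,0.829,0.833,0.995,irs
Shanghai,1,1,1,-
Jiangsu,0.896,0.909,0.985,drs
Zhejiang,1,1,1,-
Anhui,0.931,0.931,0.999,irs
Fujian,0.898,0.899,1,-
Jiangxi,1,1,1,-
Shandong,0.884,0.946,0.934,drs
Henan,1,1,1,-
Hubei,1,1,1,-
Hunan,0.989,1,0.989,drs
Guangdong,0.998,1,0.998,drs
Guangxi,1,1,1,-
Hainan,0.938,0.939,0.999,irs
Chongqing,1,1,1,-
Sichuan,1,1,1,-
Guizhou,1,1,1,-
Yunnan,1,1,1,-
Tibet,1,1,1,-
Shaanxi,0.839,0.841,0.997,irs
Gansu,0.973,0.975,0.998,drs
Qinghai,0.997,1,0.997,drs
Ningxia,1,1,1,-
Xinjiang,1,1,1,-
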