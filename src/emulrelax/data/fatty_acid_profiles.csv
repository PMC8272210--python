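code,name,beef_percent,beef_sd,pork_percent,pork_sd
C10:0,capric acid,0.043,0.001,0.059,0.001
C12:0,lauric acid,0.058,0.001,0.073,0.001
C13:0,tridecanoic acid,0.012,0.001,,
C14:0,myristic acid,2.622,0.020,1.365,0.009
C14:1,oleomyristic acid,0.423,0.003,0.068,0.001
C15:0,pentadecanoic acid,0.499,0.001,0.117,0.001
C16:0,palmitic acid,26.493,1.035,23.761,2.014
C16:1,palmitoleic acid,2.760,0.014,2.340,0.089
C17:0,heptadecanoic acid,1.382,0.032,0.524,0.004
C18:0,stearic acid,21.405,0.912,17.855,1.009
C18:1,oleic acid,38.734,3.012,41.572,2.392
C18:2,linoleic acid,4.276,0.015,7.375,0.012
C18:3,linolenic acid,0.678,0.001,0.702,0.003
C20:0,arachidic acid,0.319,0.001,0.234,0.002
C20:1,gadoleic acid,0.289,0.001,1.033,0.004
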