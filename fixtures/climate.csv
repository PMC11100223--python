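# synthetic fixture, seed=20240517
species,Ele,Lat,Lon,AMT,MTWQ,MTDQ,APRE,PREWQ,PREDQ,AI
sp01,2772.1105,53.5929,105.5879,5.4649,17.441,-12.6319,835.2752,369.5205,28.2513,0.6972
sp02,2414.254,31.1932,122.0887,13.7924,14.7342,-4.6847,373.3603,412.1438,16.5701,0.4982
sp03,2159.938,32.3539,96.2412,6.0077,12.1741,-2.5487,829.6198,107.9937,54.9879,0.7865
sp04,2922.0216,42.9598,106.3344,-6.3872,19.0723,-12.2652,267.7585,601.5056,22.459,0.2689
sp05,1911.7271,21.8995,90.7522,7.2939,13.7934,-2.7583,761.2044,445.0591,42.3476,0.5643
sp06,2246.0333,29.7278,98.5229,5.768,15.223,-4.9105,496.6786,284.0594,19.903,0.6674
sp07,2614.5149,42.5294,102.1493,-2.9146,11.9158,-2.1353,228.6663,276.3519,6.633,0.5011
sp08,2821.7787,51.6472,93.8316,5.6962,13.7142,-9.8186,667.2628,237.7164,8.3685,1.0543
sp09,2875.7046,46.9068,118.443,1.3046,10.7093,-7.5272,517.0059,504.4819,29.226,0.5646
sp10,3659.3417,39.1898,94.8916,-3.8818,20.3036,-1.0783,725.7039,398.9207,27.1328,0.4083
sp11,1016.7025,25.7891,98.8361,4.9957,12.4971,-2.7511,203.1622,424.56,28.6258,0.7741
sp12,2552.5733,23.2069,101.0327,0.1886,15.0537,-11.2114,812.5491,213.0973,33.4773,0.5115
sp13,1926.0906,29.0174,91.7264,10.7672,18.511,-6.1246,510.3386,331.1462,8.8052,0.3619
sp14,2412.0768,51.7213,116.0582,7.2648,12.5794,-10.8971,952.32,403.0166,24.1146,0.5922
sp15,2787.7143,51.4447,81.3326,6.7234,11.9011,1.5238,552.964,250.3785,12.2766,0.9076
sp16,2816.4355,39.9775,111.2541,5.4242,21.1199,-11.0173,858.8074,558.898,20.7452,0.9841
sp17,2706.6631,41.7278,104.8006,7.0331,19.2452,-4.2658,854.7867,131.6065,71.2537,0.4611
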