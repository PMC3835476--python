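# pfhaqlink crosswalk v1
# name: published-ra-crosswalk
# model: PCM
# note: Rasch-based PF-10 <-> HAQ-DI concordance table calibrated on a Dutch RA registry (n = 1791); packaged as published data, not recomputed.
method,direction,observed,observed_norm,predicted,predicted_norm
SDI,haq_to_pf10,0.000,,95,54.9
SDI,haq_to_pf10,0.125,,90,52.8
SDI,haq_to_pf10,0.250,,85,50.7
SDI,haq_to_pf10,0.375,,75,46.5
SDI,haq_to_pf10,0.500,,75,46.5
SDI,haq_to_pf10,0.625,,70,44.4
SDI,haq_to_pf10,0.750,,65,42.3
SDI,haq_to_pf10,0.875,,60,40.2
SDI,haq_to_pf10,1.000,,55,38.1
SDI,haq_to_pf10,1.125,,50,36.0
SDI,haq_to_pf10,1.250,,45,33.9
SDI,haq_to_pf10,1.375,,45,33.9
SDI,haq_to_pf10,1.500,,40,31.8
SDI,haq_to_pf10,1.625,,35,29.7
SDI,haq_to_pf10,1.750,,30,27.6
SDI,haq_to_pf10,1.875,,25,25.5
SDI,haq_to_pf10,2.000,,20,23.4
SDI,haq_to_pf10,2.125,,20,23.4
SDI,haq_to_pf10,2.250,,15,21.3
SDI,haq_to_pf10,2.375,,10,19.2
SDI,haq_to_pf10,2.500,,5,17.0
SDI,haq_to_pf10,2.625,,5,17.0
SDI,haq_to_pf10,2.750,,0,14.9
SDI,haq_to_pf10,2.875,,0,14.9
SDI,haq_to_pf10,3.000,,0,14.9
SDI,pf10_to_haq,100,57.0,0.000,
SDI,pf10_to_haq,95,54.9,0.000,
SDI,pf10_to_haq,90,52.8,0.125,
SDI,pf10_to_haq,85,50.7,0.250,
SDI,pf10_to_haq,80,48.6,0.250,
SDI,pf10_to_haq,75,46.5,0.375,
SDI,pf10_to_haq,70,44.4,0.625,
SDI,pf10_to_haq,65,42.3,0.750,
SDI,pf10_to_haq,60,40.2,0.875,
SDI,pf10_to_haq,55,38.1,1.000,
SDI,pf10_to_haq,50,36.0,1.125,
SDI,pf10_to_haq,45,33.9,1.375,
SDI,pf10_to_haq,40,31.8,1.500,
SDI,pf10_to_haq,35,29.7,1.625,
SDI,pf10_to_haq,30,27.6,1.750,
SDI,pf10_to_haq,25,25.5,1.875,
SDI,pf10_to_haq,20,23.4,2.125,
SDI,pf10_to_haq,15,21.3,2.250,
SDI,pf10_to_haq,10,19.2,2.375,
SDI,pf10_to_haq,5,17.0,2.625,
SDI,pf10_to_haq,0,14.9,2.750,
ADI,haq_to_pf10,0.000,,95,54.9
ADI,haq_to_pf10,0.125,,85,50.7
ADI,haq_to_pf10,0.250,,80,48.6
ADI,haq_to_pf10,0.375,,75,46.5
ADI,haq_to_pf10,0.500,,70,44.4
ADI,haq_to_pf10,0.625,,65,42.3
ADI,haq_to_pf10,0.750,,55,38.1
ADI,haq_to_pf10,0.875,,50,36.0
ADI,haq_to_pf10,1.000,,45,33.9
ADI,haq_to_pf10,1.125,,45,33.9
ADI,haq_to_pf10,1.250,,40,31.8
ADI,haq_to_pf10,1.375,,35,29.7
ADI,haq_to_pf10,1.500,,30,27.6
ADI,haq_to_pf10,1.625,,25,25.5
ADI,haq_to_pf10,1.750,,25,25.5
ADI,haq_to_pf10,1.875,,25,25.5
ADI,haq_to_pf10,2.000,,20,23.4
ADI,haq_to_pf10,2.125,,15,21.3
ADI,haq_to_pf10,2.250,,10,19.2
ADI,haq_to_pf10,2.375,,10,19.2
ADI,haq_to_pf10,2.500,,5,17.0
ADI,haq_to_pf10,2.625,,5,17.0
ADI,haq_to_pf10,2.750,,0,14.9
ADI,haq_to_pf10,2.875,,0,14.9
ADI,haq_to_pf10,3.000,,0,14.9
ADI,pf10_to_haq,100,57.0,0.000,
ADI,pf10_to_haq,95,54.9,0.000,
ADI,pf10_to_haq,90,52.8,0.125,
ADI,pf10_to_haq,85,50.7,0.125,
ADI,pf10_to_haq,80,48.6,0.250,
ADI,pf10_to_haq,75,46.5,0.375,
ADI,pf10_to_haq,70,44.4,0.500,
ADI,pf10_to_haq,65,42.3,0.625,
ADI,pf10_to_haq,60,40.2,0.625,
ADI,pf10_to_haq,55,38.1,0.750,
ADI,pf10_to_haq,50,36.0,1.000,
ADI,pf10_to_haq,45,33.9,1.125,
ADI,pf10_to_haq,40,31.8,1.250,
ADI,pf10_to_haq,35,29.7,1.375,
ADI,pf10_to_haq,30,27.6,1.500,
ADI,pf10_to_haq,25,25.5,1.750,
ADI,pf10_to_haq,20,23.4,2.000,
ADI,pf10_to_haq,15,21.3,2.125,
ADI,pf10_to_haq,10,19.2,2.250,
ADI,pf10_to_haq,5,17.0,2.625,
ADI,pf10_to_haq,0,14.9,2.750,
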