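drug,analyte,species,clearance_ml_per_day
DNIB0600A,total,mouse,0.18
DNIB0600A,total,rat,3.98
DNIB0600A,total,monkey,46.55
DNIB0600A,total,human,854
DMOT4039A,total,mouse,0.19
DMOT4039A,total,monkey,96.6
DMOT4039A,total,human,1400
DSTP3086S,total,mouse,0.20
DSTP3086S,total,rat,2.37
DSTP3086S,total,monkey,46.9
DSTP3086S,total,human,574
T-DM1,total,mouse,0.16
T-DM1,total,rat,1.62
T-DM1,total,monkey,16.1
T-DM1,total,human,343
T-DM1,conjugate,mouse,0.38
T-DM1,conjugate,rat,4.6
T-DM1,conjugate,monkey,41.9
T-DM1,conjugate,human,600
Thiomab,total,mouse,0.10
Thiomab,total,rat,2.15
Thiomab,total,monkey,20.37
Thiomab,total,human,200
Thiomab,conjugate,mouse,0.40
Thiomab,conjugate,rat,6.03
Thiomab,conjugate,monkey,54.25
Thiomab,conjugate,human,759
Polatuzumab vedotin,total,mouse,0.11
Polatuzumab vedotin,total,rat,4
Polatuzumab vedotin,total,monkey,24.2
Polatuzumab vedotin,total,human,1015
Pinatuzumab vedotin,total,mouse,0.12
Pinatuzumab vedotin,total,monkey,32.9
Pinatuzumab vedotin,total,human,966
Brentuximab vedotin,total,mouse,0.50
Brentuximab vedotin,total,rat,2.25
Brentuximab vedotin,total,monkey,51.1
Brentuximab vedotin,total,human,742
Anti-5T4,total,mouse,0.39
Anti-5T4,total,rat,3.3
Anti-5T4,total,monkey,27.1
Anti-5T4,total,human,360
Anti-5T4,conjugate,mouse,0.68
Anti-5T4,conjugate,rat,4.8
Anti-5T4,conjugate,monkey,52.6
Anti-5T4,conjugate,human,700
ADC1,total,mouse,0.13
ADC1,total,monkey,36.7
ADC1,total,human,756
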