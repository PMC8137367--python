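worker_type,age_group,year,births,deaths
white_collar,15-19,1995,349,7
white_collar,20-24,1995,17223,159
white_collar,25-29,1995,68742,421
white_collar,30-34,1995,61697,383
white_collar,35-39,1995,18846,172
white_collar,40-44,1995,2201,27
white_collar,45-49,1995,66,2
white_collar,15-19,2000,282,6
white_collar,20-24,2000,14179,104
white_collar,25-29,2000,69122,349
white_collar,30-34,2000,66455,334
white_collar,35-39,2000,24755,135
white_collar,40-44,2000,3005,37
white_collar,45-49,2000,81,2
white_collar,15-19,2005,201,4
white_collar,20-24,2005,9280,55
white_collar,25-29,2005,51992,207
white_collar,30-34,2005,75780,315
white_collar,35-39,2005,31073,142
white_collar,40-44,2005,4412,30
white_collar,45-49,2005,124,0
white_collar,15-19,2010,164,2
white_collar,20-24,2010,9651,52
white_collar,25-29,2010,59709,172
white_collar,30-34,2010,91809,334
white_collar,35-39,2010,55301,226
white_collar,40-44,2010,9111,74
white_collar,45-49,2010,210,1
white_collar,15-19,2015,182,0
white_collar,20-24,2015,9375,33
white_collar,25-29,2015,68660,207
white_collar,30-34,2015,114390,316
white_collar,35-39,2015,74888,254
white_collar,40-44,2015,17652,91
white_collar,45-49,2015,445,3
blue_collar,15-19,1995,230,5
blue_collar,20-24,1995,5185,45
blue_collar,25-29,1995,13048,93
blue_collar,30-34,1995,9471,73
blue_collar,35-39,1995,2754,26
blue_collar,40-44,1995,366,16
blue_collar,45-49,1995,21,4
blue_collar,15-19,2000,225,2
blue_collar,20-24,2000,3341,18
blue_collar,25-29,2000,9207,62
blue_collar,30-34,2000,7381,46
blue_collar,35-39,2000,2551,20
blue_collar,40-44,2000,378,9
blue_collar,45-49,2000,18,0
blue_collar,15-19,2005,118,0
blue_collar,20-24,2005,2398,11
blue_collar,25-29,2005,6011,31
blue_collar,30-34,2005,6798,35
blue_collar,35-39,2005,2765,11
blue_collar,40-44,2005,424,9
blue_collar,45-49,2005,15,0
blue_collar,15-19,2010,130,2
blue_collar,20-24,2010,2737,9
blue_collar,25-29,2010,6543,38
blue_collar,30-34,2010,7410,31
blue_collar,35-39,2010,4268,39
blue_collar,40-44,2010,799,8
blue_collar,45-49,2010,10,0
blue_collar,15-19,2015,140,0
blue_collar,20-24,2015,2644,6
blue_collar,25-29,2015,7373,36
blue_collar,30-34,2015,8612,29
blue_collar,35-39,2015,5545,31
blue_collar,40-44,2015,1309,11
blue_collar,45-49,2015,23,1
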