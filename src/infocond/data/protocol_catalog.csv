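exp,protocol,n_subjects,paradigm,contingency,tone_s,tone_kind,tone_values,iti_s,iri_s,tones_per_session,printed_cum_c_min,printed_cum_iti_min,printed_rewards_per_session,printed_rate_tone,printed_rate_context,printed_rate_iti,printed_iota
1,1,8,pavlovian,negative,10,fixed,,20,20,32,16.0,10.7,32,0,2.00,3.00,1.5
1,2,8,pavlovian,negative,20,fixed,,20,20,32,21.3,10.7,32,0,1.50,3.00,2.0
1,3,8,pavlovian,negative,40,fixed,,20,20,32,32.0,10.7,32,0,1.00,3.00,3.0
1,4,8,pavlovian,negative,80,fixed,,20,20,32,53.3,10.7,32,0,0.60,3.00,5.0
1,5,8,pavlovian,zero,37.5,mixed,10|20|40|80,20,20,32,30.7,10.7,32,1.04,1.04,1.04,1.0
2,6,8,pavlovian,negative,10,fixed,,20,20,32,16.0,10.7,32,0,2.00,3.00,1.5
2,7,8,pavlovian,negative,40,fixed,,20,20,32,32.0,10.7,32,0,1.00,3.00,3.0
2,8,8,pavlovian,negative,10,fixed,,50,50,32,32.0,26.7,32,0,1.00,1.20,1.2
2,9,8,pavlovian,negative,10,fixed,,20,20,128,64.0,42.7,128,0,2.00,3.00,1.5
3,10,8,pavlovian,negative,30,fixed,,20,20,32,26.7,10.7,32,0,1.20,3.00,2.5
3,11,8,pavlovian,negative,30,exponential_mean,,20,20,32,26.7,10.7,32,0,1.20,3.00,2.5
3,12,8,pavlovian,negative,50,fixed,,20,20,32,37.3,10.7,32,0,0.86,3.00,3.5
3,13,8,pavlovian,negative,50,exponential_mean,,20,20,32,37.3,10.7,32,0,0.86,3.00,3.5
4,14,8,pavlovian,negative,20,fixed,,20,20,32,21.3,10.7,32,0,1.50,3.00,2.0
4,15,8,pavlovian,negative,40,fixed,,20,20,32,32.0,10.7,32,0,1.00,3.00,3.0
4,16,7,pavlovian,negative,20,fixed,,20,40,32,21.3,10.7,16,0,0.75,1.50,2.0
4,17,8,pavlovian,negative,40,fixed,,20,40,32,32.0,10.7,16,0,0.50,1.50,3.0
4,18,8,pavlovian,negative,80,fixed,,20,40,32,53.3,10.7,16,0,0.30,1.50,5.0
5,19,12,pavlovian,negative,30,fixed,,20,20,32,26.7,10.7,32,0,1.20,3.00,2.5
5,20,12,pavlovian,negative,60,fixed,,20,20,32,42.7,10.7,32,0,0.75,3.00,4.0
5,21,12,pavlovian,negative,30,fixed,,80,20,8,14.7,10.7,32,0,2.18,3.00,1.4
5,22,12,pavlovian,negative,60,fixed,,80,20,8,18.7,10.7,32,0,1.71,3.00,1.8
6,23,8,pavlovian,negative,80,fixed,,80,20,8,21.3,10.7,32,0,1.50,3.00,2.0
6,24,8,pavlovian,negative,80,fixed,,20,20,8,13.3,2.7,8,0,0.60,3.00,5.0
6,25,8,pavlovian,negative,160,fixed,,20,20,32,96.0,10.7,32,0,0.33,3.00,9.0
6,26,8,pavlovian,negative,80,fixed,,10,20,64,96.0,10.7,32,0,0.33,3.00,9.0
7,27,6,operant,negative,80,fixed,,40,20,20,40.0,13.3,40,0,1.00,3.00,3.0
7,28,4,operant,zero,80,fixed,,40,60,20,40.0,13.3,40,1.0,1.00,1.00,1.0
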