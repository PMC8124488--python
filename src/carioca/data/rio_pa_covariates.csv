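area_id,airport,industry_pct,traffic_category,traffic_score,construction,seaport,tunnel_category,tunnel_score
PA1,1,0.00,69-85,3,1,1,6-15,3
PA2.1,1,0.00,>=96,5,1,1,16-30,4
PA2.2,0,0.00,86-95,4,1,0,1-5,2
PA3.1,1,0.00,56-68,2,1,1,0,1
PA3.2,0,0.00,69-85,3,1,0,1-5,2
PA3.3,0,0.78,86-95,4,1,0,0,1
PA4,0,0.00,>=96,5,1,0,>30,5
PA5.1,0,0.00,0-55,1,1,0,1-5,2
PA5.2,0,2.76,56-68,2,0,0,1-5,2
PA5.3,0,10.2,0-55,1,0,0,0,1
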