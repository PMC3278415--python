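scenario,block,p10,p50,p90
charcoal_traditional,private,-5.6,-1.1,1.8
charcoal_traditional,social_basic,-5.7,-0.9,2.3
charcoal_traditional,offset_basic,-5.5,-0.9,2.2
charcoal_traditional,offset_extended,-8.1,1.7,18.1
wood_ics,private,-1.6,0.2,3.3
wood_ics,social_basic,-0.9,1.1,4.9
wood_ics,offset_basic,-1.2,0.8,4.4
wood_ics,offset_extended,1.5,10.0,29.3
charcoal_ics,private,-2.2,0.3,4.1
charcoal_ics,social_basic,-1.7,1.0,5.3
charcoal_ics,offset_basic,-1.8,0.8,5.0
charcoal_ics,offset_extended,0.7,7.9,26.4
charcoal_ics_from_charcoal,private,-0.2,1.0,3.3
charcoal_ics_from_charcoal,social_basic,0.2,1.6,4.1
charcoal_ics_from_charcoal,offset_basic,-0.1,1.3,3.8
charcoal_ics_from_charcoal,offset_extended,1.6,5.5,13.4
kerosene,private,0.1,3.6,9.4
kerosene,social_basic,0.3,4.2,10.3
kerosene,offset_basic,-0.1,3.8,9.8
kerosene,offset_extended,9.9,23.8,51.0
lpg,private,-1.1,2.3,8.1
lpg,social_basic,0.9,4.9,11.2
lpg,offset_basic,-0.7,3.0,9.2
lpg,offset_extended,8.9,22.9,50.7
electric,private,-4.7,-0.4,5.4
electric,social_basic,-4.1,1.4,7.8
electric,offset_basic,-6.6,-0.9,5.3
electric,offset_extended,4.0,18.4,46.9
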