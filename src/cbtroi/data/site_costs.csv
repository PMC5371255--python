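label,category,unit,n_units,unit_cost_kes
Diploma Nurse (25% FTE),Personnel,FTE,0.25,444240
Counselor (100% FTE),Personnel,FTE,2,201840
Sharp pointed pen,Supplies,Packet,2,500
Whiteboard markers,Supplies,Packet,2,1200
Airtime for assessment coordinator (500 KES/week x 40 weeks),Supplies,Per office,1,20000
Airtime for physician consultation (4 calls x 40 weeks),Supplies,Call,160,50
Box files,Supplies,Piece,5,155
Suspension files,Supplies,Box,2,3500
Photocopy,Supplies,Copy,2000,3
Benzodiazepines (10% of patients per year),Supplies,Patient,16,24
Multivitamins,Supplies,Patient,16,16
Participant payments (participants x 6 visits),Participant payments,Visit,960,200
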