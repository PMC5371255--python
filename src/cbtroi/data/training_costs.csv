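label,category,unit,n_units,unit_cost_kes
Counselor supervisor consultants: 2-week training plus 5 days training prep for 4 consultants,Counselor consultants,Day of pay x 4 consultants,76,2000
Supervision after training (12 sites x 18 weeks x 1 day/week),Counselor consultants,Day of pay,216,2000
Travel to sites (12 sites x 18 weeks x 1 day/week),Counselor consultants,Days of travel,216,1000
Phone consultation after training (2 calls/site/mo for 8 mos),Counselor consultants,Phone call,192,300
Medical/Psychiatry trainers: 10 day training of diploma nurses by 2 physicians,Psychiatry,Days of training,10,10000
Consultation after training and training (10% FTE for 5 years for one physician),Psychiatry,Year salary,0.5,1440000
Per diems for trainee counselors (12 days x 24 counselors),Per diems,Days of training x 24,288,3500
Per diems for trainee diploma nurses (10 days x 12 nurses),Per diems,Days of training x 12,120,3500
Training workbooks and treatment manuals,Training materials,Piece,43,900
Audiorecorders,Training materials,Piece,12,4000
Rechargeable batteries,Training materials,Piece,24,200
Battery charger,Training materials,Piece,12,1040
Posters,Training materials,Piece,36,1100
Sharp pointed pen,Training materials,Packet,2,500
Whiteboard markers,Training materials,Packet,2,1200
Conference center facility,Conference center,Days of room rental,12,12000
Lunch and tea (participants x days),Conference center,Lunches,486,900
File cabinet,Furniture,Piece,12,16500
Stacking plastic chair,Furniture,Piece,144,800
Whiteboards,Furniture,Piece,12,8500
Cellphone for calls for assessments,Equipment,Piece,12,4000
Cashbox,Equipment,Piece,12,5999
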