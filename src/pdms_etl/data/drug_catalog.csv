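drug_id,ingredient,amount,amount_unit,volume_ml,standard_unit
D001,norepinephrine,5,mg,50,mg/h
D002,propofol,1000,mg,50,mg/h
D003,heparin,25000,U,50,U/h
D004,insulin,50,U,50,U/h
D005,fentanyl,0.5,mg,50,mg/h
D006,midazolam,100,mg,50,mg/h
D007,furosemide,250,mg,50,mg/h
D008,amiodarone,900,mg,50,mg/h
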