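compound,mechanism,fold_50um,fold_6p25um
Temozolomide,Base alkylation,2.57,1.04
Pipobroman,Base alkylation,2.55,1.25
Thiotepa,Base alkylation,2.43,1.50
Chlorambucil,Base alkylation,2.30,1.30
Benzophenanthridine,Topoisomerase II inhibitor,2.36,0.60
Teniposide,Topoisomerase II inhibitor,1.66,0.93
Etoposide,Topoisomerase II inhibitor,0.41,1.95
Mitoxantrone,Topoisomerase II inhibitor,Toxic,0.20
Cisplatin,Intrastrand crosslinker,2.12,0.93
Oxaliplatin,Intrastrand crosslinker,1.93,1.08
Carboplatin,Intrastrand crosslinker,1.59,1.26
Bleomycin,Interstrand crosslinker,3.31,1.71
Thioguanine,Purine synthesis inhibitor,3.39,1.60
Pentostatin,Adenosine deaminase inhibitor,1.57,0.63
Cladribine,Adenosine deaminase inhibitor,1.65,1.42
Deoxyadenosine,Adenosine deaminase inhibitor,1.75,1.17
Doxorubicin,Alkylator,1.12,2.12
Valrubicin,Alkylator,1.88,1.46
Cytaribine,DNA polymerase inhibitor,2.42,1.92
Docetaxel,Tubulin stabilizer,1.66,1.38
Arsenic trioxide,Thioredoxin reductase inhibitor,3.42,1.54
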