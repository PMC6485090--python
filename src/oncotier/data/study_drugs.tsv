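sample	drugs	trials
GBM1	BKM120|INC280	NCT01870726 NCT02386826
GBM3	BKM120	NCT01870726 NCT01349660
GBM4	Cetuximab|Everolimus	NCT01238237 NCT01870726
GBM5	Nilotinib	NCT01140568 NCT01871311
GBM6	BKM120|Everolimus|Cetuximab	NCT02142803 NCT01349660 NCT01238237
GBM7	Vismodegib|MEK162	NCT00980343 NCT01885195
GBM8	Pembrolizumab|Nivolumab	NCT02337686 NCT02017717
GBM9	Cetuximab|ABT41|Bevacizumab|BKM120	NCT02573324 NCT01349660
GBM10	Temozolomide|Everolimus|MEK162	NCT01885195
GBM12	BKM120|Afatanib	NCT01349660 NCT01934361
GBM13	RG7112/RG7388|AMG232|Palbociclib|Everolimus	NCT01877382 NCT02143635 NCT01227434 NCT01870726
GBM14	BKM-120|Everolimus	NCT01349660 NCT01934361 NCT01870726
GBM15	BKM-120|Cetuximab|ABT-414|Afatanib|ABBV-221|Palbociclib|Ribociclib|Everolimus	NCT01339052 NCT02423525 NCT02573324 NCT02365662 NCT01227434 NCT02345824
GBM16	Everolimus|Cetuximab|ABT-414|Afatanib|ABBV-221|Nilotinib|Crenolanib	NCT02423525 NCT02573324 NCT02365662 NCT02626364 NCT01140568 NCT01871311
GBM17	Vemurafanib|Cobimetinib|ABT414	NCT02537600 NCT02573324 NCT02423525
GBM21	Cetuximab|ABT-414|Afatanib|ABBV-221|Crizotinib|INC280|Everolimus|Palbociclib|Ribociclib	NCT02423525 NCT02573324 NCT02365662 NCT02540161 NCT02034981 NCT02386826 NCT01227434
GBM22	Everolimus|Olaparib|Veliparib|MEK162|Temsirolimus/Docetaxel	NCT01390571 NCT02152892
GBM23	AG-120|AG-881|BAY-1436032|Everolimus|INK128	NCT02073994 NCT02481154 NCT02746081 NCT01434602 NCT02142803
GBM24	BKM-120|Cetuximab|ABT-414|Afatanib|ABBV-221|Crizotinib|INC280|Everolimus|Palbociclib|Ribociclib|Olaparib|Veliparib	NCT01870726 NCT01339052 NCT02423525 NCT02573324 NCT02365662 NCT02386826 NCT01227434 NCT02345824 NCT01390571 NCT02152982
GBM25	Pembrolizumab|Nivolumab|Paclitaxel|Nilotinib	NCT02337686 NCT02017717 NCT02379416 NCT01140568 NCT01871311
GBM26	BKM-120|RG-7112|AMG-232|Palbociclib|Ribociclib|Everolimus	NCT01249660 NCT01339052 NCT01877282 NCT01723020 NCT01390571 NCT02152982 NCT02255461
GBM27	Afatnib|Rindopepimut|CAR-T|Cetuximab|ABT-414|Afatanib|Palbociclib|Ribociclib|Everolimus	NCT01480479 NCT02423525 NCT02664363 NCT02573324 NCT02423525 NCT00703625 NCT01390571 NCT02152982
GBM28	BKM-120|Crizotinib|INC280|Nilotinib|Palbociclib|Ribociclib|Everolimus	NCT01870726 NCT01339052 NCT01870726 NCT01339052 NCT02365662 NCT01140568 NCT01390571 NCT02152982
GBM29	Cetuximab|ABT-414|Afatanib|Everolimus|Palbociclib|Ribociclib	NCT02573324 NCT02423525 NCT0070362 NCT01390571 NCT02152982 NCT01390571 NCT02152982
GBM31	AG-120|AG-881|BAY-1436032|Everolimus|Temsirolimus|MLN0128|Temsirolimus/Docetaxel|Palbociclib|Ribociclib	NCT02073994 NCT02481154 NCT02746081 NCT002238946 NCT02142803 NCT01390571 NCT02152982
GBM32	BKM-120|Olaparib|Veliparib|Everolimus	NCT01870726 NCT01390571 NCT02152982 NCT01434602
GBM33	Everolimus|Temsirolimus|Palbociclib|Ribociclib	NCT01390571 NCT02152982
GBM34	Cetuximab|ABT-414|Afatanib|Everolimus|Temsirolimus|Docetaxel|CP-0610|MK-8628|GSK2820151	NCT02573324 NCT02423525 NCT00703625 NCT02698176 NCT02630251 NCT01877382
GBM35	Cetuximab|ABT-414|Afatanib|BKM-120|Palbociclib|Ribociclib|Everolimus|Imatinib|Nilotinib	NCT02573324 NCT02423525 NCT02345824 NCT01390571 NCT02152982
GBM36	MEK162|Temsirolimus|Docetaxel	NCT00703625
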