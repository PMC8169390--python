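sponsor,due,timely,late,unreported,pct_unreported
"Birkbeck, University of London",1,0,0,1,100.0
Cardiff University,19,0,0,19,100.0
Imperial College London,224,8,79,137,61.2
King's College London,86,0,4,82,95.3
Liverpool School of Tropical Medicine,6,0,1,5,83.3
London School of Hygiene and Tropical Medicine,159,2,7,150,94.3
Newcastle University,17,0,1,16,94.1
Queen Mary University of London,33,0,7,26,78.8
"Queen's University, Belfast",36,0,2,34,94.4
"St George's, University of London",32,0,0,32,100.0
University College London,107,0,6,101,94.4
University of Aberdeen,44,1,0,43,97.7
University of Birmingham,35,0,0,35,100.0
University of Bristol,10,0,1,9,90.0
University of Cambridge,33,0,0,33,100.0
University of Dundee,70,0,5,65,92.9
University of Edinburgh,99,1,3,95,96.0
University of Exeter,27,0,0,27,100.0
University of Glasgow,37,1,1,35,94.6
University of Leeds,59,2,3,54,91.5
University of Leicester,25,0,0,25,100.0
University of Liverpool,20,0,1,19,95.0
University of Manchester,42,1,1,40,95.2
University of Nottingham,126,2,5,119,94.4
University of Oxford,234,7,11,216,92.3
University of Sheffield,20,0,0,20,100.0
University of Southampton,22,1,1,20,90.9
University of Sussex,5,0,0,5,100.0
University of Warwick,5,0,1,4,80.0
University of York,1,0,0,1,100.0
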