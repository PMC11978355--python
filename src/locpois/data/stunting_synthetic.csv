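y,x1,x2
24,4.7769760497350564,2.012845181767954
35,0.66721837047661348,8.753454057570055
309,0.13998739365084664,21.416531464066356
73,3.1165352063742437,9.2822178455221991
57,5.8770432729093747,4.91323278085168
342,6.0305830394304953,17.34839033756182
81,11.660821181739975,3.6022832107837415
41,8.2940031710497468,1.2117747136576691
110,4.6048295810995077,10.516407594799022
236,4.2142361674908191,16.727845442995246
57,0.42702252062196561,10.245215815015383
25,4.4400622762338937,1.8033055975336372
35,4.1472581966095943,3.8675973739746663
28,0.83057785825377539,3.8612639060839138
14,0.74758825843317278,1.4781823682498705
106,0.13463374425428237,14.411806303345388
335,5.2183618026992997,17.732532607746577
158,8.0174446007839801,9.258642406862803
20,1.6956306350537229,2.1215756020973515
23,1.3873938014067164,2.0483171410847172
454,8.7196658817236106,16.605627308591409
90,3.1846658987535528,9.1526731312231799
133,6.7936612747886702,11.087699991772082
21,0.028516716607202858,2.8406403681237058
72,2.0390026362171323,9.8186386746635268
28,0.00035727819414528404,3.4532949058457465
52,10.507059716982376,0.80484136096316727
41,0.097269197614971048,6.9856851223273031
122,6.127956456679482,9.3525923549394854
26,1.5531557183991818,2.6329244695077385
829,11.363885364445352,18.856610562957677
29,3.1800210720807667,2.7997370338695298
194,10.098273498749485,9.7602918976638495
24,0.46673943738446266,3.3636998552113093
99,7.8844469101205314,7.4657867151504371
25,0.12998984384455001,5.5858009356187841
50,3.3655364631084086,5.8669782642423449
33,1.4236387829729864,4.2273660198664409
63,3.8134174927167854,6.6189959392199151
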