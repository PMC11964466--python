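phase,dataset,row,quartile,n_groups,n_people,d_population
GI1DA,A,Great Britain,Q1,19.4,826,0.016
GI1DA,A,Great Britain,Q2,10.1,431,0.008
GI1DA,A,Great Britain,Q3,8.8,374,0.007
GI1DA,A,N France,Q1,7.5,317,0.016
GI1DA,A,N France,Q2,3.9,166,0.008
GI1DA,A,N France,Q3,3.4,144,0.007
GI1DA,A,Benelux & NW Germany,Q1,35.2,1496,0.016
GI1DA,A,Benelux & NW Germany,Q2,18.4,781,0.008
GI1DA,A,Benelux & NW Germany,Q3,15.9,678,0.007
GI1DA,A,S Scandinavia,Q1,10.4,441,0.016
GI1DA,A,S Scandinavia,Q2,5.4,230,0.008
GI1DA,A,S Scandinavia,Q3,4.7,200,0.007
GI1DA,A,Poland & NE Germany,Q1,50.0,2125,0.016
GI1DA,A,Poland & NE Germany,Q2,26.1,1109,0.008
GI1DA,A,Poland & NE Germany,Q3,22.6,962,0.007
GI1DA,A,Czech Rep. & SE Germany,Q1,109.7,4661,0.040
GI1DA,A,Czech Rep. & SE Germany,Q2,59.5,2529,0.022
GI1DA,A,Czech Rep. & SE Germany,Q3,44.1,1876,0.016
GI1DA,A,Switzerland & SW Germany,Q1,12.9,547,0.016
GI1DA,A,Switzerland & SW Germany,Q2,9.4,402,0.012
GI1DA,A,Switzerland & SW Germany,Q3,3.9,165,0.005
GI1DA,A,Italy,Q1,5.8,246,0.016
GI1DA,A,Italy,Q2,4.2,180,0.012
GI1DA,A,Italy,Q3,1.7,74,0.005
GI1DA,A,SE France,Q1,9.8,415,0.016
GI1DA,A,SE France,Q2,7.2,305,0.012
GI1DA,A,SE France,Q3,2.9,125,0.005
GI1DA,A,SW France,Q1,24.9,1058,0.027
GI1DA,A,SW France,Q2,15.6,662,0.017
GI1DA,A,SW France,Q3,1.9,81,0.002
GI1DA,A,Spain & French Pyrenees,Q1,44.2,1878,0.027
GI1DA,A,Spain & French Pyrenees,Q2,27.6,1175,0.017
GI1DA,A,Spain & French Pyrenees,Q3,3.4,143,0.002
GI1DA,A,Portugal,Q1,5.9,252,0.027
GI1DA,A,Portugal,Q2,3.7,158,0.017
GI1DA,A,Portugal,Q3,0.5,19,0.002
GI1DA,A,SUM,Q1,336,14262,0.022
GI1DA,A,SUM,Q2,191,8126,0.013
GI1DA,A,SUM,Q3,114,4839,0.008
GI1DA,A,TAC,Q2,,,0.003
GS1,A,Great Britain,Q1,8.8,374,0.014
GS1,A,Great Britain,Q2,5.0,212,0.008
GS1,A,Great Britain,Q3,3.5,147,0.006
GS1,A,N France,Q1,4.8,202,0.014
GS1,A,N France,Q2,2.7,114,0.008
GS1,A,N France,Q3,1.9,79,0.006
GS1,A,Benelux & NW Germany,Q1,17.9,761,0.014
GS1,A,Benelux & NW Germany,Q2,10.1,430,0.008
GS1,A,Benelux & NW Germany,Q3,7.0,299,0.006
GS1,A,S Scandinavia,Q1,0.5,20,0.014
GS1,A,S Scandinavia,Q2,0.3,11,0.008
GS1,A,S Scandinavia,Q3,0.2,8,0.006
GS1,A,Poland & NE Germany,Q1,50.8,2159,0.014
GS1,A,Poland & NE Germany,Q2,28.7,1221,0.008
GS1,A,Poland & NE Germany,Q3,20.0,849,0.006
GS1,A,Czech Rep. & SE Germany,Q1,55.3,2352,0.044
GS1,A,Czech Rep. & SE Germany,Q2,10.8,460,0.009
GS1,A,Czech Rep. & SE Germany,Q3,3.6,154,0.003
GS1,A,Switzerland & SW Germany,Q1,7.3,310,0.013
GS1,A,Switzerland & SW Germany,Q2,5.3,226,0.010
GS1,A,Switzerland & SW Germany,Q3,2.3,98,0.004
GS1,A,Italy,Q1,10.3,437,0.013
GS1,A,Italy,Q2,7.5,319,0.010
GS1,A,Italy,Q3,3.3,138,0.004
GS1,A,SE France,Q1,6.2,262,0.013
GS1,A,SE France,Q2,4.5,191,0.010
GS1,A,SE France,Q3,2.0,83,0.004
GS1,A,SW France,Q1,10.2,434,0.018
GS1,A,SW France,Q2,5.7,242,0.010
GS1,A,SW France,Q3,1.9,80,0.003
GS1,A,Spain & French Pyrenees,Q1,31.3,1329,0.018
GS1,A,Spain & French Pyrenees,Q2,17.5,742,0.010
GS1,A,Spain & French Pyrenees,Q3,5.8,246,0.003
GS1,A,Portugal,Q1,3.6,154,0.018
GS1,A,Portugal,Q2,2.0,86,0.010
GS1,A,Portugal,Q3,0.7,28,0.003
GS1,A,SUM,Q1,207,8794,0.018
GS1,A,SUM,Q2,100,4254,0.009
GS1,A,SUM,Q3,52,2209,0.005
GS1,A,TAC,Q2,,,0.002
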