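region,phase,dataset,block,odi_km2,q1,q2,q3,n_raw
Great Britain,GI1DA,A,north,51900,2670,5117,5896,17
N France,GI1DA,A,north,19940,2670,5117,5896,17
Benelux & NW Germany,GI1DA,A,north,94010,2670,5117,5896,17
S Scandinavia,GI1DA,A,north,27700,2670,5117,5896,17
Poland & NE Germany,GI1DA,A,north,133500,2670,5117,5896,17
Czech Rep. & SE Germany,GI1DA,A,czech,115900,1057,1948,2626,10
Switzerland & SW Germany,GI1DA,A,alpine,33540,2604,3550,8662,19
Italy,GI1DA,A,alpine,15050,2604,3550,8662,19
SE France,GI1DA,A,alpine,25440,2604,3550,8662,19
SW France,GI1DA,A,southwest,39290,1578,2522,20730,7
Spain & French Pyrenees,GI1DA,A,southwest,69720,1578,2522,20730,7
Portugal,GI1DA,A,southwest,9351,1578,2522,20730,7
Great Britain,GS1,A,north,25830,2934,5187,7462,4
N France,GS1,A,north,13950,2934,5187,7462,4
Benelux & NW Germany,GS1,A,north,52500,2934,5187,7462,4
S Scandinavia,GS1,A,north,1350,2934,5187,7462,4
Poland & NE Germany,GS1,A,north,149000,2934,5187,7462,4
Czech Rep. & SE Germany,GS1,A,czech,53670,970,4959,14826,11
Switzerland & SW Germany,GS1,A,alpine,23050,3160,4336,9988,14
Italy,GS1,A,alpine,32500,3160,4336,9988,14
SE France,GS1,A,alpine,19480,3160,4336,9988,14
SW France,GS1,A,southwest,24740,2420,4337,13094,10
Spain & French Pyrenees,GS1,A,southwest,75710,2420,4337,13094,10
Portugal,GS1,A,southwest,8780,2420,4337,13094,10
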