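library	category	unique	total
CK	total	3360437	18127561
CK	miRNA	20156	1680180
CK	rRNA	68092	1333046
CK	snRNA	4561	17456
CK	snoRNA	2399	4918
CK	tRNA	6374	162311
CK	unannotated	3258855	14929650
Cr200	total	6172992	19552260
Cr200	miRNA	43980	2057888
Cr200	rRNA	101446	2552322
Cr200	snRNA	10311	48852
Cr200	snoRNA	2979	6596
Cr200	tRNA	12242	260269
Cr200	unannotated	6002034	14626333
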