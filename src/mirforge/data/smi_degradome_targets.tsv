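mirna	transcript	length	annotation
hbr-miR396a_R-3	gi51954849gbCV165709.1CV165709	437	T-complex protein 1 subunit zeta
ppt-miR166m_R-3	gi51955619gbCV166479.1CV166479	500	S-adenosylmethionine synthetase
ppt-miR166m_R-3	gi51958718gbCV169578.1CV169578	490	S-adenosylmethionine synthetase
ppt-miR166m_R-3	gi51958974gbCV169834.1CV169834	525	S-adenosylmethionine synthetase
ppt-miR166m_R-3	gi51959843gbCV170703.1CV170703	517	S-adenosylmethionine synthetase
osa-miR5072_L-4_1ss13GA	gi51958299gbCV169159.1CV169159	498	peroxidase
osa-miR5072_L-4_1ss13GA	gi51958400gbCV169260.1CV169260	693	peroxidase
smo-miR396_R+1_1ss7GA	gi51952605gbCV163465.1CV163465	526	nucleolin
smo-miR396_R+1_1ss7GA	gi51953108gbCV163968.1CV163968	420	nucleolin
aly-miR858-5p_L-1R+1_1ss5GA	gi51952052gbCV162912.1CV162912	620	myb proto-oncogene protein, plant
aly-miR858-5p_L-1R+1_1ss5GA	gi51955967gbCV166827.1CV166827	548	myb proto-oncogene protein, plant
aly-miR858-5p_L-1R+1_1ss5GA	gi51957272gbCV168132.1CV168132	490	myb proto-oncogene protein, plant
aly-miR858-5p_L-1R+1_1ss5GA	gi51958934gbCV169794.1CV169794	544	myb proto-oncogene protein, plant
ppt-miR166m_R-3	gi51953523gbCV164383.1CV164383	482	large subunit ribosomal protein L9e
zma-miR482-5p_R-1_1ss1TC	gi51952323gbCV163183.1CV163183	464	elongation factor EF-1 alpha subunit
zma-miR482-5p_R-1_1ss1TC	gi51956430gbCV167290.1CV167290	716	elongation factor EF-1 alpha subunit
zma-miR482-5p_R-1_1ss1TC	gi51958162gbCV169022.1CV169022	496	elongation factor EF-1 alpha subunit
zma-miR482-5p_R-1_1ss1TC	gi51958761gbCV169621.1CV169621	592	elongation factor EF-1 alpha subunit
zma-miR482-5p_R-1_1ss1TC	gi51959562gbCV170422.1CV170422	618	elongation factor EF-1 alpha subunit
zma-miR482-5p_R-1_1ss1TC	gi51960584gbCV171444.1CV171444	617	elongation factor EF-1 alpha subunit
osa-miR5072_L-4_1ss13GA	gi51952295gbCV163155.1CV163155	635	carboxymethylenebutenolidase
mtr-miR2673a_L-1_1ss21AT	gi51951421gbCV162281.1CV162281	645	calmodulin
mtr-miR2673a_L-1_1ss21AT	gi51956749gbCV167609.1CV167609	482	calmodulin
aly-miR319a-5p_L-1R-1_1ss19TG	gi51957938gbCV168798.1CV168798	486	calmodulin
aly-miR319a-5p_L-1R-1_1ss19TG	gi51958940gbCV169800.1CV169800	539	calmodulin
aly-miR319a-5p_L-1R-1_1ss19TG	gi51959542gbCV170402.1CV170402	561	calmodulin
aly-miR319a-5p_L-1R-1_1ss19TG	gi51960600gbCV171460.1CV171460	557	calmodulin
ppt-miR166m_R-3	gi51956695gbCV167555.1CV167555	488	aquaporin TIP
osa-miR5072_L-4_1ss13GA	gi51953064gbCV163924.1CV163924	389	acetyl-CoA C-acetyltransferase
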