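mp,species,group,molar_row_length_mm,mass_kg,ln_mass
16,Kerberos langebadreae,Hyai,60.9,87.69,11.38
16,Paroxyaena galliae,Hyai,50.9,46.72,10.75
17a,Paroxyaena galliae,Hyai,50.9,46.72,10.75
17a,Hyaenodon brachyrhynchus,Hyae,38.2,17.06,9.74
17a,Hyaenodon minor,Hyae,30.4,7.65,8.94
17a,Hyaenodon requieni,Hyae,48.1,38.30,10.55
17b,Paroxyaena galliae,Hyai,50.9,46.72,10.75
17b,Hyaenodon brachyrhynchus,Hyae,38.2,17.06,9.74
17b,Hyaenodon minor,Hyae,30.4,7.65,8.94
17b,Hyaenodon requieni,Hyae,48.1,38.30,10.55
18,Pterodon dasyuroides,Hyai,52.35,51.56,10.85
18,Parapterodon lostangensis,Hyai,62.82,97.78,11.49
18,Paroxyaena pavlovi,Hyai,50.9,46.72,10.75
18,Hyaenodon brachyrhynchus,Hyae,38.2,17.06,9.74
18,Hyaenodon heberti,Hyae,45.09,30.53,10.33
18,Hyaenodon minor,Hyae,30.4,7.65,8.94
18,Hyaenodon requieni,Hyae,48.1,38.30,10.55
18,Hyaenodon rossignoli,Hyae,26.1,4.48,8.41
19,Pterodon dasyuroides,Hyai,52.35,51.56,10.85
19,Parapterodon lostangensis,Hyai,62.82,97.78,11.49
19,Paroxyaena pavlovi,Hyai,50.9,46.72,10.75
19,Hyaenodon brachyrhynchus,Hyae,38.2,17.06,9.74
19,Hyaenodon heberti,Hyae,45.09,30.53,10.33
19,Hyaenodon requieni,Hyae,48.1,38.30,10.55
19,Hyaenodon rossignoli,Hyae,26.1,4.48,8.41
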