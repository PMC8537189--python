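species_id,theta_water_deg,theta_water_sd,theta_diiodomethane_deg,theta_diiodomethane_sd,gamma_polar,gamma_dispersive,gamma_total
LiLu,76.3,8.8,55.9,1.7,9.1,25.4,34.5
CeDe,68.8,9.7,58.7,6.3,15.0,22.0,37.0
PiTa,84.3,4.6,54.9,3.9,4.6,27.8,32.4
PiBu,73.3,8.5,62.1,7.4,12.8,20.8,33.6
ViOd,73.5,7.3,55.2,5.6,10.7,25.2,35.9
PiTo,80.4,4.6,62.9,3.7,8.3,21.9,30.2
BuSi,83.4,9.4,54.9,5.8,5.0,27.6,32.6
PhSe,63.3,8.6,49.5,8.7,16.2,26.4,42.6
InTe,87.5,10.4,58.7,3.5,3.9,26.1,30.0
PhSu,83.4,7.2,56.5,4.4,5.3,26.7,32.0
TrFo,59.7,10.3,55.1,5.9,20.9,22.5,43.4
MaGr,68.2,14.2,54.4,3.7,14.1,24.5,38.6
ErJa,49.7,15.4,50.1,8.5,27.3,23.5,50.8
OsFr,71.4,6.0,51.1,3.7,11.0,27.2,38.2
PlOr,66.3,10.5,46.3,6.9,13.2,28.9,42.1
TrRe,131.2,4.3,104.9,4.4,0.1,7.3,7.4
JaMe,80.1,7.4,63.5,6.1,8.7,21.5,30.2
IlCo,90.6,10.1,59.9,9.4,2.9,26.1,29.0
FaJa,68.7,6.9,51.7,4.7,12.9,26.3,39.2
NaDo,73.2,4.5,55.9,5.3,11.0,24.7,35.7
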