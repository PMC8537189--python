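species_id,scale,fraction,value
LiLu,leaf,DPM,22.5
LiLu,leaf,PM_0.1-2.5,5.3
LiLu,leaf,PM_2.5-10,10.8
LiLu,leaf,PM_>10,71.6
LiLu,leaf,SPM,110.2
LiLu,plant,DPM,999.5
LiLu,plant,PM_0.1-2.5,236.2
LiLu,plant,PM_2.5-10,481.6
LiLu,plant,PM_>10,3189.3
LiLu,plant,SPM,4906.6
LiLu,land,DPM,73.2
LiLu,land,PM_0.1-2.5,17.3
LiLu,land,PM_2.5-10,35.3
LiLu,land,PM_>10,233.5
LiLu,land,SPM,359.3
CeDe,leaf,DPM,15.1
CeDe,leaf,PM_0.1-2.5,2.0
CeDe,leaf,PM_2.5-10,9.4
CeDe,leaf,PM_>10,47.4
CeDe,leaf,SPM,73.9
CeDe,plant,DPM,2953.2
CeDe,plant,PM_0.1-2.5,399.2
CeDe,plant,PM_2.5-10,1836.1
CeDe,plant,PM_>10,9260.5
CeDe,plant,SPM,14449.0
CeDe,land,DPM,55.1
CeDe,land,PM_0.1-2.5,7.5
CeDe,land,PM_2.5-10,34.3
CeDe,land,PM_>10,172.8
CeDe,land,SPM,269.7
PiTa,leaf,DPM,25.9
PiTa,leaf,PM_0.1-2.5,4.1
PiTa,leaf,PM_2.5-10,8.2
PiTa,leaf,PM_>10,74.7
PiTa,leaf,SPM,112.9
PiTa,plant,DPM,594.5
PiTa,plant,PM_0.1-2.5,93.6
PiTa,plant,PM_2.5-10,187.2
PiTa,plant,PM_>10,1736.6
PiTa,plant,SPM,2611.9
PiTa,land,DPM,49.8
PiTa,land,PM_0.1-2.5,7.8
PiTa,land,PM_2.5-10,15.7
PiTa,land,PM_>10,145.4
PiTa,land,SPM,218.7
PiBu,leaf,DPM,14.9
PiBu,leaf,PM_0.1-2.5,2.2
PiBu,leaf,PM_2.5-10,6.7
PiBu,leaf,PM_>10,42.0
PiBu,leaf,SPM,65.8
PiBu,plant,DPM,192.2
PiBu,plant,PM_0.1-2.5,29.0
PiBu,plant,PM_2.5-10,86.9
PiBu,plant,PM_>10,542.5
PiBu,plant,SPM,850.6
PiBu,land,DPM,27.6
PiBu,land,PM_0.1-2.5,4.2
PiBu,land,PM_2.5-10,12.5
PiBu,land,PM_>10,77.8
PiBu,land,SPM,122.1
ViOd,leaf,DPM,23.9
ViOd,leaf,PM_0.1-2.5,6.3
ViOd,leaf,PM_2.5-10,10.6
ViOd,leaf,PM_>10,93.5
ViOd,leaf,SPM,134.3
ViOd,plant,DPM,48.7
ViOd,plant,PM_0.1-2.5,12.9
ViOd,plant,PM_2.5-10,21.6
ViOd,plant,PM_>10,190.6
ViOd,plant,SPM,273.8
ViOd,land,DPM,99.3
ViOd,land,PM_0.1-2.5,26.3
ViOd,land,PM_2.5-10,44.2
ViOd,land,PM_>10,388.8
ViOd,land,SPM,558.6
PiTo,leaf,DPM,22.5
PiTo,leaf,PM_0.1-2.5,4.7
PiTo,leaf,PM_2.5-10,5.3
PiTo,leaf,PM_>10,69.4
PiTo,leaf,SPM,101.9
PiTo,plant,DPM,49.7
PiTo,plant,PM_0.1-2.5,12.9
PiTo,plant,PM_2.5-10,21.6
PiTo,plant,PM_>10,190.6
PiTo,plant,SPM,274.8
PiTo,land,DPM,98.8
PiTo,land,PM_0.1-2.5,20.7
PiTo,land,PM_2.5-10,23.4
PiTo,land,PM_>10,305.3
PiTo,land,SPM,448.2
BuSi,leaf,DPM,15.3
BuSi,leaf,PM_0.1-2.5,2.0
BuSi,leaf,PM_2.5-10,5.9
BuSi,leaf,PM_>10,31.6
BuSi,leaf,SPM,54.8
BuSi,plant,DPM,4.7
BuSi,plant,PM_0.1-2.5,0.6
BuSi,plant,PM_2.5-10,1.8
BuSi,plant,PM_>10,9.6
BuSi,plant,SPM,16.7
BuSi,land,DPM,41.0
BuSi,land,PM_0.1-2.5,5.5
BuSi,land,PM_2.5-10,15.9
BuSi,land,PM_>10,84.8
BuSi,land,SPM,147.2
PhSe,leaf,DPM,20.4
PhSe,leaf,PM_0.1-2.5,2.9
PhSe,leaf,PM_2.5-10,4.5
PhSe,leaf,PM_>10,65.3
PhSe,leaf,SPM,93.1
PhSe,plant,DPM,386.2
PhSe,plant,PM_0.1-2.5,54.1
PhSe,plant,PM_2.5-10,85.0
PhSe,plant,PM_>10,1235.9
PhSe,plant,SPM,1761.2
PhSe,land,DPM,87.6
PhSe,land,PM_0.1-2.5,12.3
PhSe,land,PM_2.5-10,19.3
PhSe,land,PM_>10,280.2
PhSe,land,SPM,399.4
InTe,leaf,DPM,12.9
InTe,leaf,PM_0.1-2.5,2.9
InTe,leaf,PM_2.5-10,5.5
InTe,leaf,PM_>10,36.7
InTe,leaf,SPM,58.0
InTe,plant,DPM,3.9
InTe,plant,PM_0.1-2.5,0.9
InTe,plant,PM_2.5-10,1.7
InTe,plant,PM_>10,11.1
InTe,plant,SPM,17.6
InTe,land,DPM,32.4
InTe,land,PM_0.1-2.5,7.2
InTe,land,PM_2.5-10,13.9
InTe,land,PM_>10,92.6
InTe,land,SPM,146.1
PhSu,leaf,DPM,12.9
PhSu,leaf,PM_0.1-2.5,1.4
PhSu,leaf,PM_2.5-10,6.5
PhSu,leaf,PM_>10,34.5
PhSu,leaf,SPM,55.3
PhSu,plant,DPM,2.2
PhSu,plant,PM_0.1-2.5,0.2
PhSu,plant,PM_2.5-10,1.1
PhSu,plant,PM_>10,5.9
PhSu,plant,SPM,9.4
PhSu,land,DPM,17.4
PhSu,land,PM_0.1-2.5,1.9
PhSu,land,PM_2.5-10,8.8
PhSu,land,PM_>10,46.6
PhSu,land,SPM,74.7
TrFo,leaf,DPM,36.1
TrFo,leaf,PM_0.1-2.5,3.1
TrFo,leaf,PM_2.5-10,8.8
TrFo,leaf,PM_>10,74.9
TrFo,leaf,SPM,122.9
TrFo,plant,DPM,246.8
TrFo,plant,PM_0.1-2.5,20.9
TrFo,plant,PM_2.5-10,60.0
TrFo,plant,PM_>10,511.6
TrFo,plant,SPM,839.3
TrFo,land,DPM,75.5
TrFo,land,PM_0.1-2.5,6.4
TrFo,land,PM_2.5-10,18.3
TrFo,land,PM_>10,156.5
TrFo,land,SPM,256.7
MaGr,leaf,DPM,19.8
MaGr,leaf,PM_0.1-2.5,4.7
MaGr,leaf,PM_2.5-10,6.7
MaGr,leaf,PM_>10,81.4
MaGr,leaf,SPM,112.6
MaGr,plant,DPM,588.7
MaGr,plant,PM_0.1-2.5,139.6
MaGr,plant,PM_2.5-10,200.3
MaGr,plant,PM_>10,2421.7
MaGr,plant,SPM,3350.3
MaGr,land,DPM,77.0
MaGr,land,PM_0.1-2.5,18.3
MaGr,land,PM_2.5-10,26.2
MaGr,land,PM_>10,316.8
MaGr,land,SPM,438.3
ErJa,leaf,DPM,28.2
ErJa,leaf,PM_0.1-2.5,2.7
ErJa,leaf,PM_2.5-10,8.8
ErJa,leaf,PM_>10,94.1
ErJa,leaf,SPM,133.8
ErJa,plant,DPM,421.2
ErJa,plant,PM_0.1-2.5,38.7
ErJa,plant,PM_2.5-10,131.3
ErJa,plant,PM_>10,1407.1
ErJa,plant,SPM,1998.3
ErJa,land,DPM,64.2
ErJa,land,PM_0.1-2.5,6.1
ErJa,land,PM_2.5-10,20.0
ErJa,land,PM_>10,214.5
ErJa,land,SPM,304.8
OsFr,leaf,DPM,26.1
OsFr,leaf,PM_0.1-2.5,2.7
OsFr,leaf,PM_2.5-10,10.8
OsFr,leaf,PM_>10,70.8
OsFr,leaf,SPM,110.4
OsFr,plant,DPM,169.7
OsFr,plant,PM_0.1-2.5,17.2
OsFr,plant,PM_2.5-10,70.3
OsFr,plant,PM_>10,460.0
OsFr,plant,SPM,717.2
OsFr,land,DPM,61.1
OsFr,land,PM_0.1-2.5,6.2
OsFr,land,PM_2.5-10,25.3
OsFr,land,PM_>10,165.7
OsFr,land,SPM,258.3
PlOr,leaf,DPM,35.3
PlOr,leaf,PM_0.1-2.5,4.9
PlOr,leaf,PM_2.5-10,12.5
PlOr,leaf,PM_>10,117.1
PlOr,leaf,SPM,169.8
PlOr,plant,DPM,1080.1
PlOr,plant,PM_0.1-2.5,149.8
PlOr,plant,PM_2.5-10,380.8
PlOr,plant,PM_>10,3583.7
PlOr,plant,SPM,5194.4
PlOr,land,DPM,79.1
PlOr,land,PM_0.1-2.5,11.0
PlOr,land,PM_2.5-10,27.9
PlOr,land,PM_>10,262.4
PlOr,land,SPM,380.4
TrRe,leaf,DPM,5.3
TrRe,leaf,PM_0.1-2.5,1.0
TrRe,leaf,PM_2.5-10,2.5
TrRe,leaf,PM_>10,13.9
TrRe,leaf,SPM,22.7
TrRe,plant,DPM,0.1
TrRe,plant,PM_0.1-2.5,0.1
TrRe,plant,PM_2.5-10,0.1
TrRe,plant,PM_>10,0.1
TrRe,plant,SPM,0.4
TrRe,land,DPM,15.0
TrRe,land,PM_0.1-2.5,2.9
TrRe,land,PM_2.5-10,6.9
TrRe,land,PM_>10,39.3
TrRe,land,SPM,64.1
JaMe,leaf,DPM,19.8
JaMe,leaf,PM_0.1-2.5,1.6
JaMe,leaf,PM_2.5-10,8.6
JaMe,leaf,PM_>10,42.0
JaMe,leaf,SPM,72.0
JaMe,plant,DPM,7.2
JaMe,plant,PM_0.1-2.5,0.6
JaMe,plant,PM_2.5-10,3.1
JaMe,plant,PM_>10,15.4
JaMe,plant,SPM,26.3
JaMe,land,DPM,40.0
JaMe,land,PM_0.1-2.5,3.3
JaMe,land,PM_2.5-10,17.3
JaMe,land,PM_>10,84.9
JaMe,land,SPM,145.5
IlCo,leaf,DPM,14.7
IlCo,leaf,PM_0.1-2.5,1.4
IlCo,leaf,PM_2.5-10,5.3
IlCo,leaf,PM_>10,53.9
IlCo,leaf,SPM,75.3
IlCo,plant,DPM,154.1
IlCo,plant,PM_0.1-2.5,15.0
IlCo,plant,PM_2.5-10,55.7
IlCo,plant,PM_>10,565.2
IlCo,plant,SPM,790.0
IlCo,land,DPM,39.8
IlCo,land,PM_0.1-2.5,3.9
IlCo,land,PM_2.5-10,14.4
IlCo,land,PM_>10,146.0
IlCo,land,SPM,204.1
FaJa,leaf,DPM,26.1
FaJa,leaf,PM_0.1-2.5,3.7
FaJa,leaf,PM_2.5-10,8.8
FaJa,leaf,PM_>10,77.1
FaJa,leaf,SPM,115.7
FaJa,plant,DPM,161.9
FaJa,plant,PM_0.1-2.5,22.8
FaJa,plant,PM_2.5-10,54.4
FaJa,plant,PM_>10,478.0
FaJa,plant,SPM,717.1
FaJa,land,DPM,88.0
FaJa,land,PM_0.1-2.5,12.4
FaJa,land,PM_2.5-10,29.6
FaJa,land,PM_>10,260.0
FaJa,land,SPM,390.0
NaDo,leaf,DPM,21.2
NaDo,leaf,PM_0.1-2.5,2.7
NaDo,leaf,PM_2.5-10,7.3
NaDo,leaf,PM_>10,49.0
NaDo,leaf,SPM,80.2
NaDo,plant,DPM,61.1
NaDo,plant,PM_0.1-2.5,7.6
NaDo,plant,PM_2.5-10,21.2
NaDo,plant,PM_>10,141.0
NaDo,plant,SPM,230.9
NaDo,land,DPM,64.3
NaDo,land,PM_0.1-2.5,8.0
NaDo,land,PM_2.5-10,22.3
NaDo,land,PM_>10,148.4
NaDo,land,SPM,243.0
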