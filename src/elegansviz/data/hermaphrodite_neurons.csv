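cell_name,class_name
ADAL,ADA
ADAR,ADA
ADEL,ADE
ADER,ADE
ADFL,ADF
ADFR,ADF
ADLL,ADL
ADLR,ADL
AFDL,AFD
AFDR,AFD
AIAL,AIA
AIAR,AIA
AIBL,AIB
AIBR,AIB
AIML,AIM
AIMR,AIM
AINL,AIN
AINR,AIN
AIYL,AIY
AIYR,AIY
AIZL,AIZ
AIZR,AIZ
ALA,ALA
ALML,ALM
ALMR,ALM
ALNL,ALN
ALNR,ALN
AQR,AQR
AS1,AS
AS2,AS
AS3,AS
AS4,AS
AS5,AS
AS6,AS
AS7,AS
AS8,AS
AS9,AS
AS10,AS
AS11,AS
ASEL,ASE
ASER,ASE
ASGL,ASG
ASGR,ASG
ASHL,ASH
ASHR,ASH
ASIL,ASI
ASIR,ASI
ASJL,ASJ
ASJR,ASJ
ASKL,ASK
ASKR,ASK
AUAL,AUA
AUAR,AUA
AVAL,AVA
AVAR,AVA
AVBL,AVB
AVBR,AVB
AVDL,AVD
AVDR,AVD
AVEL,AVE
AVER,AVE
AVFL,AVF
AVFR,AVF
AVG,AVG
AVHL,AVH
AVHR,AVH
AVJL,AVJ
AVJR,AVJ
AVKL,AVK
AVKR,AVK
AVL,AVL
AVM,AVM
AWAL,AWA
AWAR,AWA
AWBL,AWB
AWBR,AWB
AWCL,AWC
AWCR,AWC
BAGL,BAG
BAGR,BAG
BDUL,BDU
BDUR,BDU
CANL,CAN
CANR,CAN
CEPDL,CEP
CEPDR,CEP
CEPVL,CEP
CEPVR,CEP
DA1,DA
DA2,DA
DA3,DA
DA4,DA
DA5,DA
DA6,DA
DA7,DA
DA8,DA
DA9,DA
DB1,DB
DB2,DB
DB3,DB
DB4,DB
DB5,DB
DB6,DB
DB7,DB
DD1,DD
DD2,DD
DD3,DD
DD4,DD
DD5,DD
DD6,DD
DVA,DVA
DVB,DVB
DVC,DVC
FLPL,FLP
FLPR,FLP
HSNL,HSN
HSNR,HSN
I1L,I1
I1R,I1
I2L,I2
I2R,I2
I3,I3
I4,I4
I5,I5
I6,I6
IL1DL,IL1
IL1DR,IL1
IL1L,IL1
IL1R,IL1
IL1VL,IL1
IL1VR,IL1
IL2DL,IL2
IL2DR,IL2
IL2L,IL2
IL2R,IL2
IL2VL,IL2
IL2VR,IL2
LUAL,LUA
LUAR,LUA
M1,M1
M2L,M2
M2R,M2
M3L,M3
M3R,M3
M4,M4
M5,M5
MCL,MC
MCR,MC
MI,MI
NSML,NSM
NSMR,NSM
OLLL,OLL
OLLR,OLL
OLQDL,OLQ
OLQDR,OLQ
OLQVL,OLQ
OLQVR,OLQ
PDA,PDA
PDB,PDB
PDEL,PDE
PDER,PDE
PHAL,PHA
PHAR,PHA
PHBL,PHB
PHBR,PHB
PHCL,PHC
PHCR,PHC
PLML,PLM
PLMR,PLM
PLNL,PLN
PLNR,PLN
PQR,PQR
PVCL,PVC
PVCR,PVC
PVDL,PVD
PVDR,PVD
PVM,PVM
PVNL,PVN
PVNR,PVN
PVPL,PVP
PVPR,PVP
PVQL,PVQ
PVQR,PVQ
PVR,PVR
PVT,PVT
PVWL,PVW
PVWR,PVW
RIAL,RIA
RIAR,RIA
RIBL,RIB
RIBR,RIB
RICL,RIC
RICR,RIC
RID,RID
RIFL,RIF
RIFR,RIF
RIGL,RIG
RIGR,RIG
RIH,RIH
RIML,RIM
RIMR,RIM
RIPL,RIP
RIPR,RIP
RIR,RIR
RIS,RIS
RIVL,RIV
RIVR,RIV
RMDDL,RMD
RMDDR,RMD
RMDL,RMD
RMDR,RMD
RMDVL,RMD
RMDVR,RMD
RMED,RME
RMEL,RME
RMER,RME
RMEV,RME
RMFL,RMF
RMFR,RMF
RMGL,RMG
RMGR,RMG
RMHL,RMH
RMHR,RMH
SAADL,SAA
SAADR,SAA
SAAVL,SAA
SAAVR,SAA
SABD,SAB
SABVL,SAB
SABVR,SAB
SDQL,SDQ
SDQR,SDQ
SIADL,SIA
SIADR,SIA
SIAVL,SIA
SIAVR,SIA
SIBDL,SIB
SIBDR,SIB
SIBVL,SIB
SIBVR,SIB
SMBDL,SMB
SMBDR,SMB
SMBVL,SMB
SMBVR,SMB
SMDDL,SMD
SMDDR,SMD
SMDVL,SMD
SMDVR,SMD
URADL,URA
URADR,URA
URAVL,URA
URAVR,URA
URBL,URB
URBR,URB
URXL,URX
URXR,URX
URYDL,URY
URYDR,URY
URYVL,URY
URYVR,URY
VA1,VA
VA2,VA
VA3,VA
VA4,VA
VA5,VA
VA6,VA
VA7,VA
VA8,VA
VA9,VA
VA10,VA
VA11,VA
VA12,VA
VB1,VB
VB2,VB
VB3,VB
VB4,VB
VB5,VB
VB6,VB
VB7,VB
VB8,VB
VB9,VB
VB10,VB
VB11,VB
VC1,VC
VC2,VC
VC3,VC
VC4,VC
VC5,VC
VC6,VC
VD1,VD
VD2,VD
VD3,VD
VD4,VD
VD5,VD
VD6,VD
VD7,VD
VD8,VD
VD9,VD
VD10,VD
VD11,VD
VD12,VD
VD13,VD
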