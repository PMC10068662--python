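local_label,concept_id,vocabulary,domain
MAP,3027598,LOINC,Measurement
SBP,3004249,LOINC,Measurement
DBP,3012888,LOINC,Measurement
HR,3027018,LOINC,Measurement
SPO2,3016502,LOINC,Measurement
ETCO2,3035357,LOINC,Measurement
TV,3024882,LOINC,Measurement
mmHg,8876,UCUM,Unit
bpm,8541,UCUM,Unit
%,8554,UCUM,Unit
mL,8587,UCUM,Unit
mg,8576,UCUM,Unit
ug,9655,UCUM,Unit
g,8504,UCUM,Unit
ng/L,8845,UCUM,Unit
g/dL,8713,UCUM,Unit
umol/L,8749,UCUM,Unit
propofol,753626,RxNorm,Drug
sufentanil,19078219,RxNorm,Drug
rocuronium,19003953,RxNorm,Drug
ephedrine,1125315,RxNorm,Drug
cefazolin,1771162,RxNorm,Drug
HSTNT,3033745,LOINC,Measurement
HB,3000963,LOINC,Measurement
CREAT,3016723,LOINC,Measurement
I10,45600001,ICD10,Condition
I20.9,45600002,ICD10,Condition
I25.1,45600003,ICD10,Condition
I48,45600004,ICD10,Condition
I50.9,45600005,ICD10,Condition
E11.9,45600006,ICD10,Condition
E66.9,45600007,ICD10,Condition
E78.5,45600008,ICD10,Condition
J44.9,45600009,ICD10,Condition
J45.9,45600010,ICD10,Condition
N18.3,45600011,ICD10,Condition
N18.5,45600012,ICD10,Condition
K80.2,45600013,ICD10,Condition
K35.8,45600014,ICD10,Condition
C18.9,45600015,ICD10,Condition
C34.9,45600016,ICD10,Condition
C61,45600017,ICD10,Condition
M16.9,45600018,ICD10,Condition
M17.9,45600019,ICD10,Condition
S72.0,45600020,ICD10,Condition
I71.4,45600021,ICD10,Condition
I65.2,45600022,ICD10,Condition
D64.9,45600023,ICD10,Condition
F32.9,45600024,ICD10,Condition
Z95.1,45600025,ICD10,Condition
HHFA016,2100000001,local,Procedure
HMFC004,2100000002,local,Procedure
NEKA020,2100000003,local,Procedure
NFKA007,2100000004,local,Procedure
JVJF004,2100000005,local,Procedure
GFFA004,2100000006,local,Procedure
HFFA011,2100000007,local,Procedure
DZEA003,2100000008,local,Procedure
DDMA006,2100000009,local,Procedure
EBLA002,2100000010,local,Procedure
DGAA004,2100000011,local,Procedure
JQGA002,2100000012,local,Procedure
LMMA012,2100000013,local,Procedure
QZFA036,2100000014,local,Procedure
FELF004,2100000015,local,Procedure
EQQF001,2100000016,local,Procedure
EQQF002,2100000017,local,Procedure
EQLF001,2100000018,local,Procedure
EQLF002,2100000019,local,Procedure
EQQP004,2100000020,local,Procedure
anesthesia_start,4174061,SNOMED,Observation
anesthesia_end,4174062,SNOMED,Observation
surgery_start,4301351,SNOMED,Observation
surgery_end,4301352,SNOMED,Observation
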