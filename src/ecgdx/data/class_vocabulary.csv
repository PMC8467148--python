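# Scored diagnosis vocabulary: 24 classes after merging equivalent pairs
# (CRBBB<->RBBB, PAC<->SVPB, PVC<->VEB; merged entries carry both code sets).
# SNOMED CT codes are externally sourced configuration (PhysioNet/CinC Challenge
# 2020 public scoring list); the codes are editable, the abbreviations are the
# engine's canonical class names.
abbreviation,codes,name,is_normal
IAVB,270492004,1st degree AV block,0
AF,164889003,Atrial Fibrillation,0
AFL,164890007,Atrial Flutter,0
Brady,426627000,Bradycardia,0
RBBB,713427006;59118001,Complete/Right Bundle Branch Block,0
IRBBB,713426002,Incomplete Right Bundle Branch Block,0
LAnFB,445118002,Left Anterior Fascicular Block,0
LAD,39732003,Left Axis Deviation,0
LBBB,164909002,Left Bundle Branch Block,0
LQRSV,251146004,Low QRS Voltage,0
NSIVCB,698252002,Nonspecific Intraventricular Conduction Disorder,0
PR,10370003,Pacing Rhythm,0
PAC,284470004;63593006,Premature Atrial Contraction/Supraventricular Premature Beats,0
PVC,427172004;17338001,Premature Ventricular Contraction/Ventricular Ectopic Beats,0
LQT,111975006,Prolonged QT Interval,0
LPR,164947007,Prolonged PR Interval,0
QAb,164917005,Q Wave Abnormal,0
RAD,47665007,Right Axis Deviation,0
SA,427393009,Sinus Arrhythmia,0
SB,426177001,Sinus Bradycardia,0
NSR,426783006,Normal Sinus Rhythm,1
STach,427084000,Sinus Tachycardia,0
Tab,164934002,T Wave Abnormal,0
TInv,59931005,T Wave Inversion,0
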