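pattern,severity,label
H21.0,MB,Hyphema
H31.3,MB,Hemorrhage and rupture of the choroid
H35.6,MB,"Retinal, vitreous, or subarachnoid hemorrhage"
H43.1,MB,"Retinal, vitreous, or subarachnoid hemorrhage"
I60_,MB,"Retinal, vitreous, or subarachnoid hemorrhage"
I31.2,MB,Hemopericardium not classified elsewhere
I61_,MB,Intracerebral hemorrhage
I62_,MB,Other nontraumatic intracranial hemorrhages
K66.1,MB,Hemoperitoneum
M25.0_,MB,Hemarthrosis
R57.1,MB,Hypovolemic shock
T81.1,MB,"Shock during or after a procedure for diagnostic and therapeutic purposes, not classified elsewhere"
H11.3,CRNMB,Conjunctival hemorrhage
H92.2,CRNMB,Otorrhagia
I85.0,CRNMB,Hemorrhagic esophageal varices
I98.3,CRNMB,Hemorrhagic esophageal varices
K22.8,CRNMB,Other specified diseases of the esophagus
J94.2,CRNMB,Non-traumatic hemothorax
K25.0,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K25.2,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K25.6,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K26.0,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K26.2,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K26.4,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K26.6,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K27.0,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K27.2,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K27.4,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K27.6,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K28.0,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K28.2,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K28.4,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K28.6,CRNMB,"Gastric, duodenal, or gastrojejunal ulcer with hemorrhage and/or perforation"
K29.0,CRNMB,Acute hemorrhagic gastritis
K62.5,CRNMB,Rectal and anal hemorrhage
K92.0,CRNMB,Hematemesis
K92.1,CRNMB,Melena
K92.2,CRNMB,Unspecified gastrointestinal hemorrhage
N42.1,CRNMB,Prostatic congestion and hemorrhage
N83.7,CRNMB,Hematoma of the broad ligament
N85.7,CRNMB,Hematometra
N93.8,CRNMB,Abnormal bleeding from the uterus and vagina
N93.9,CRNMB,Abnormal bleeding from the uterus and vagina
N95.0,CRNMB,Postmenopausal bleeding
R04.0,CRNMB,Epistaxis
R04.1,CRNMB,Throat hemorrhage
R04.2,CRNMB,Hemoptysis
R04.8,CRNMB,Respiratory tract hemorrhage
R04.9,CRNMB,Respiratory tract hemorrhage
R23.3,CRNMB,Spontaneous ecchymosis
R31,CRNMB,Unspecified hematuria
R58,CRNMB,"Hemorrhage, not classified elsewhere"
T81.0,CRNMB,"Hemorrhage, not classified elsewhere"
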