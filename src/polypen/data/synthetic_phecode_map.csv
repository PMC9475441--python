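icd_code,phecode,category,description
Z2951A,295.1,mental disorders,schizophrenia
Z2951B,295.1,mental disorders,schizophrenia
Z2952A,295.2,mental disorders,paranoid disorders
Z2952B,295.2,mental disorders,paranoid disorders
Z2953A,295.3,mental disorders,psychosis
Z2953B,295.3,mental disorders,psychosis
Z2961A,296.1,mental disorders,bipolar disorder
Z2961B,296.1,mental disorders,bipolar disorder
Z2962A,296.2,mental disorders,major depression
Z2962B,296.2,mental disorders,major depression
Z3001A,300.1,mental disorders,anxiety disorder
Z3001B,300.1,mental disorders,anxiety disorder
Z3010A,301.0,mental disorders,personality disorder
Z3010B,301.0,mental disorders,personality disorder
Z3160A,316.0,mental disorders,substance use disorder
Z3160B,316.0,mental disorders,substance use disorder
Z3170A,317.0,mental disorders,alcohol use disorder
Z3170B,317.0,mental disorders,alcohol use disorder
Z3273A,327.3,neurological,sleep apnea
Z3273B,327.3,neurological,sleep apnea
Z3450A,345.0,neurological,epilepsy
Z3450B,345.0,neurological,epilepsy
Z3400A,340.0,neurological,migraine
Z3400B,340.0,neurological,migraine
Z2500A,250.0,endocrine/metabolic,type 2 diabetes
Z2500B,250.0,endocrine/metabolic,type 2 diabetes
Z2440A,244.0,endocrine/metabolic,hypothyroidism
Z2440B,244.0,endocrine/metabolic,hypothyroidism
Z2721A,272.1,endocrine/metabolic,hyperlipidemia
Z2721B,272.1,endocrine/metabolic,hyperlipidemia
Z2781A,278.1,endocrine/metabolic,obesity
Z2781B,278.1,endocrine/metabolic,obesity
Z4011A,401.1,circulatory system,essential hypertension
Z4011B,401.1,circulatory system,essential hypertension
Z4111A,411.1,circulatory system,ischemic heart disease
Z4111B,411.1,circulatory system,ischemic heart disease
Z4272A,427.2,circulatory system,atrial fibrillation
Z4272B,427.2,circulatory system,atrial fibrillation
Z4280A,428.0,circulatory system,heart failure
Z4280B,428.0,circulatory system,heart failure
Z4330A,433.0,circulatory system,cerebrovascular disease
Z4330B,433.0,circulatory system,cerebrovascular disease
Z3891A,389.1,sense organs,sensorineural hearing loss
Z3891B,389.1,sense organs,sensorineural hearing loss
Z3650A,365.0,sense organs,glaucoma
Z3650B,365.0,sense organs,glaucoma
Z3660A,366.0,sense organs,cataract
Z3660B,366.0,sense organs,cataract
Z4650A,465.0,respiratory,upper respiratory infection
Z4650B,465.0,respiratory,upper respiratory infection
Z4800A,480.0,respiratory,pneumonia
Z4800B,480.0,respiratory,pneumonia
Z4950A,495.0,respiratory,asthma
Z4950B,495.0,respiratory,asthma
Z4960A,496.0,respiratory,chronic airway obstruction
Z4960B,496.0,respiratory,chronic airway obstruction
Z5301A,530.1,digestive,esophagitis and reflux
Z5301B,530.1,digestive,esophagitis and reflux
Z5350A,535.0,digestive,gastritis
Z5350B,535.0,digestive,gastritis
Z5550A,555.0,digestive,inflammatory bowel disease
Z5550B,555.0,digestive,inflammatory bowel disease
Z5715A,571.5,digestive,chronic liver disease
Z5715B,571.5,digestive,chronic liver disease
Z5200A,520.0,digestive,dental disorders
Z5200B,520.0,digestive,dental disorders
Z5800A,580.0,genitourinary,chronic kidney disease
Z5800B,580.0,genitourinary,chronic kidney disease
Z6000A,600.0,genitourinary,prostatic hyperplasia
Z6000B,600.0,genitourinary,prostatic hyperplasia
Z6140A,614.0,genitourinary,urinary tract infection
Z6140B,614.0,genitourinary,urinary tract infection
Z6860A,686.0,dermatologic,skin infection
Z6860B,686.0,dermatologic,skin infection
Z6960A,696.0,dermatologic,psoriasis
Z6960B,696.0,dermatologic,psoriasis
Z7061A,706.1,dermatologic,sebaceous cyst
Z7061B,706.1,dermatologic,sebaceous cyst
Z7401A,740.1,musculoskeletal,osteoarthritis
Z7401B,740.1,musculoskeletal,osteoarthritis
Z7140A,714.0,musculoskeletal,rheumatoid arthritis
Z7140B,714.0,musculoskeletal,rheumatoid arthritis
Z7210A,721.0,musculoskeletal,spondylosis
Z7210B,721.0,musculoskeletal,spondylosis
Z7431A,743.1,musculoskeletal,osteoporosis
Z7431B,743.1,musculoskeletal,osteoporosis
Z0790A,079.0,infectious diseases,viral infection
Z0790B,079.0,infectious diseases,viral infection
Z0410A,041.0,infectious diseases,bacterial infection
Z0410B,041.0,infectious diseases,bacterial infection
Z1530A,153.0,neoplasms,colorectal cancer
Z1530B,153.0,neoplasms,colorectal cancer
Z1850A,185.0,neoplasms,prostate cancer
Z1850B,185.0,neoplasms,prostate cancer
Z4012A,401.2,circulatory system,hypertensive heart disease
Z4012B,401.2,circulatory system,hypertensive heart disease
Z4150A,415.0,circulatory system,pulmonary embolism
Z4150B,415.0,circulatory system,pulmonary embolism
Z4540A,454.0,circulatory system,varicose veins
Z4540B,454.0,circulatory system,varicose veins
Z4740A,474.0,respiratory,chronic tonsillitis
Z4740B,474.0,respiratory,chronic tonsillitis
Z5090A,509.0,respiratory,respiratory failure
Z5090B,509.0,respiratory,respiratory failure
Z5400A,540.0,digestive,appendicitis
Z5400B,540.0,digestive,appendicitis
Z5740A,574.0,digestive,cholelithiasis
Z5740B,574.0,digestive,cholelithiasis
Z5990A,599.0,genitourinary,urinary obstruction
Z5990B,599.0,genitourinary,urinary obstruction
Z7160A,716.0,musculoskeletal,other arthropathies
Z7160B,716.0,musculoskeletal,other arthropathies
Z7350A,735.0,musculoskeletal,foot deformity
Z7350B,735.0,musculoskeletal,foot deformity
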