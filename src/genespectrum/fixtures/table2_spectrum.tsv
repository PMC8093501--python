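gene	disease	category	route
ATM	Breast Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
ATM	Colorectal Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
ATM	Gastric Cancer	MALIGNANT	LITERATURE_NLP
ATM	Pancreatic Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
ATM	Prostate Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
BARD1	Breast Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
BRCA1	Breast Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
BRCA1	Ovarian Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
BRCA1	Pancreatic Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
BRCA1	Prostate Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
BRCA2	Breast Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
BRCA2	Melanoma	MALIGNANT	MAJOR_CLINGEN_NCCN
BRCA2	Ovarian Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
BRCA2	Pancreatic Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
BRCA2	Prostate Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
CDH1	Breast Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
CDH1	Gastric Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
CDH1	BCD Syndrome	BENIGN	MINOR_THREE_OF_FOUR
CHEK2	Breast Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
CHEK2	Colorectal Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
CHEK2	Gastric Cancer	MALIGNANT	LITERATURE_NLP
CHEK2	Kidney Cancer	MALIGNANT	LITERATURE_NLP
CHEK2	Prostate Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
CHEK2	Osteosarcoma	MALIGNANT	MINOR_THREE_OF_FOUR
CHEK2	Thyroid Cancer	MALIGNANT	LITERATURE_NLP
NF1	Brain Tumor	MALIGNANT	MAJOR_CLINGEN_NCCN
NF1	Breast Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
NF1	Leukemia	MALIGNANT	MINOR_THREE_OF_FOUR
NF1	Sarcoma	MALIGNANT	MAJOR_CLINGEN_NCCN
NF1	Bone Dysplasia	BENIGN	MAJOR_CLINGEN_NCCN
NF1	Cafe-Au-Lait Spots	BENIGN	MAJOR_CLINGEN_NCCN
NF1	Intellectual Disability	BENIGN	MAJOR_CLINGEN_NCCN
NF1	Iris Hamartoma	BENIGN	MAJOR_CLINGEN_NCCN
NF1	Neurofibroma	BENIGN	MAJOR_CLINGEN_NCCN
NF1	Pulmonary Stenosis	BENIGN	MINOR_THREE_OF_FOUR
NF1	Skin	BENIGN	MAJOR_CLINGEN_NCCN
NF1	GIST	BORDERLINE	MAJOR_CLINGEN_NCCN
NF1	Paraganglioma	BORDERLINE	MAJOR_CLINGEN_NCCN
NF1	Pheochromocytoma	BORDERLINE	MAJOR_CLINGEN_NCCN
PALB2	Breast Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
PALB2	Ovarian Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
PALB2	Pancreatic Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
PALB2	Prostate Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
PTEN	Brain Tumor	MALIGNANT	MAJOR_CLINGEN_NCCN
PTEN	Breast Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
PTEN	Colorectal Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
PTEN	Endometrial Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
PTEN	Kidney Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
PTEN	Melanoma	MALIGNANT	MAJOR_CLINGEN_NCCN
PTEN	Thyroid Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
PTEN	Acral Keratoses	BENIGN	MAJOR_CLINGEN_NCCN
PTEN	Autism	BENIGN	MAJOR_CLINGEN_NCCN
PTEN	Cerebrovascular Malformation	BENIGN	MAJOR_CLINGEN_NCCN
PTEN	Facial Papules	BENIGN	MAJOR_CLINGEN_NCCN
PTEN	GI Hamartomatous Polyps	BENIGN	MAJOR_CLINGEN_NCCN
PTEN	Lipoma	BENIGN	MAJOR_CLINGEN_NCCN
PTEN	Macrocephaly	BENIGN	MAJOR_CLINGEN_NCCN
PTEN	Macular Pigmentation	BENIGN	MAJOR_CLINGEN_NCCN
PTEN	Oral Mucosal Papillomatosis	BENIGN	MAJOR_CLINGEN_NCCN
PTEN	Palmoplantar Keratoses	BENIGN	MAJOR_CLINGEN_NCCN
PTEN	Thyroid	BENIGN	MAJOR_CLINGEN_NCCN
PTEN	Trichilemmoma	BENIGN	MAJOR_CLINGEN_NCCN
PTEN	Uterine Fibroid	BENIGN	MAJOR_CLINGEN_NCCN
RECQL	Breast Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
STK11	Breast Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
STK11	Cervical Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
STK11	Colorectal Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
STK11	Endometrial Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
STK11	Gastric Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
STK11	Hepatobiliary Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
STK11	Lung Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
STK11	Pancreatic Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
STK11	Small Intestine Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
STK11	GI Hamartomatous Polyps	BENIGN	MAJOR_CLINGEN_NCCN
STK11	Skin	BENIGN	MAJOR_CLINGEN_NCCN
STK11	Non-Epithelial Ovarian Tumor	BORDERLINE	MAJOR_CLINGEN_NCCN
STK11	Ovarian SCST	BORDERLINE	MAJOR_CLINGEN_NCCN
STK11	Testicular SCST	BORDERLINE	MAJOR_CLINGEN_NCCN
TP53	Adrenocortical Carcinoma	MALIGNANT	MAJOR_CLINGEN_NCCN
TP53	Brain Tumor	MALIGNANT	MAJOR_CLINGEN_NCCN
TP53	Breast Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
TP53	Colorectal Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
TP53	Hepatobiliary Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
TP53	Pancreatic Cancer	MALIGNANT	MAJOR_CLINGEN_NCCN
TP53	Osteosarcoma	MALIGNANT	MAJOR_CLINGEN_NCCN
TP53	Soft Tissue Sarcoma	MALIGNANT	MAJOR_CLINGEN_NCCN
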