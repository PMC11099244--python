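article	condition	split_label
Ahmadi et al.	ADHD	Segments
Bakhtyari and Mirzaei	ADHD	Segments
Chang et al.	ADHD	Subjects
Chen et al. (a)	ADHD	Segments
Chen et al. (b)	ADHD	Segments
Dubreuil-Vall et al.	ADHD	Subjects
Mafi and Radfar	ADHD	Segments
Moghaddari et al.	ADHD	Segments
TaghiBeyglou et al.	ADHD	Subjects
Tosun	ADHD	Segments
Vahid et al.	ADHD	Subjects
Zhou et al. (a)	ADHD	Unclear
Kim et al.	Alcoholism	Segments
Bi and Wang	Alzheimer's	Segments
Gkenios et al.	Alzheimer's	Both
Huggins et al.	Alzheimer's	Segments
Ieracitano et al.	Alzheimer's	Both
Kim and Kim	Alzheimer's	Subjects
Morabito et al.	Alzheimer's	Subjects
You et al.	Alzheimer's	Segments
Zhao and He	Alzheimer's	Segments
Acharya et al. (a)	Depression	Segments
Ay et al.	Depression	Segments
Kwon et al.	Depression	Subjects
Li et al.	Depression	Subjects
Li X. et al.	Depression	Subjects
Mumtaz and Qayyum	Depression	Segments
Uyulan et al.	Depression	Unclear
Xie et al.	Depression	Unclear
Zhang et al.	Depression	Segments
Khare et al.	Parkinson's	Segments
Lee et al.	Parkinson's	Segments
Loh et al.	Parkinson's	Segments
Oh et al. (a)	Parkinson's	Segments
Shaban	Parkinson's	Segments
Shaban and Amara	Parkinson's	Subjects
Shi et al.	Parkinson's	Subjects
Ahmedt-Aristizabal et al.	Schizophrenia	Subjects
Chu et al.	Schizophrenia	Segments
Oh et al. (b)	Schizophrenia	Both
Shalbaf et al.	Schizophrenia	Segments
Acharya et al. (b)	Seizure	Segments
Avcu et al.	Seizure	Subjects
Choi et al.	Seizure	Subjects
Daoud and Bayoumi	Seizure	Segments
Emami et al.	Seizure	Subjects
Fürbass et al.	Seizure	Subjects
Gao et al.	Seizure	Segments
Hussein et al.	Seizure	Segments
Iešmantas and Alzbutas	Seizure	Subjects
Jana et al.	Seizure	Segments
Khan et al.	Seizure	Segments
Li Y. et al.	Seizure	Segments
Liang et al.	Seizure	Segments
Raghu et al.	Seizure	Unclear
Rashed-Al-Mahfuz et al.	Seizure	Segments
Truong et al.	Seizure	Segments
Ullah et al.	Seizure	Segments
Wei et al. (a)	Seizure	Segments
Wei et al. (b)	Seizure	Segments
Zhao et al.	Seizure	Segments
Zhou et al. (b)	Seizure	Segments
Bouallegue et al.	Seizure and autism	Segments
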