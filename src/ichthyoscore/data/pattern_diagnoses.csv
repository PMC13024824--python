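pattern,diagnosis,new_nomenclature,clinical_cues
I,Ichthyosis vulgaris,FLG-nEDD,palmoplantar_hyperlinearity;atopy
I,X-linked ichthyosis,STS-sEDD,male_sex;coarse_lamellar_scaling;coarse_dark_scaling;flexures_spared;summer_improvement;no_palmoplantar_hyperlinearity;cryptorchidism
I,Acquired ichthyosis,,late_onset;comorbidities
I,Conradi-Huenermann-Happle syndrome,EBP-sEDD,
I,Harlequin ichthyosis,ABCA12-nEDD,erythroderma;ectropion;eclabium
I,Ichthyosis follicularis with alopecia and photophobia (IFAP) syndrome,MBTPS2-sEDD-IFAP,
I,Keratitis ichthyosis deafness (KID) syndrome,GJB2-sEDD-KID,brownish_hyperkeratosis
I,Sjoegren-Larsson syndrome,ALDH3A2-sEDD,cobblestone_hyperkeratosis;severe_pruritus
II,Autosomal recessive congenital ichthyosis (erythrodermic),ARCI-nEDD,fine_scaling;mild_erythroderma
II,Autosomal recessive congenital ichthyosis (non-erythrodermic),ARCI-nEDD,coarse_dark_scaling
II,Bathing suit ichthyosis,TGM1-nEDD,coarse_dark_scaling;bathing_suit_distribution
II,Harlequin ichthyosis,ABCA12-nEDD,erythroderma;ectropion;eclabium
II,X-linked ichthyosis,STS-sEDD,male_sex;coarse_lamellar_scaling;coarse_dark_scaling;flexures_spared;summer_improvement;no_palmoplantar_hyperlinearity;cryptorchidism
II,Sjoegren-Larsson syndrome,ALDH3A2-sEDD,cobblestone_hyperkeratosis;severe_pruritus
II,Ichthyosis follicularis with alopecia and photophobia (IFAP) syndrome,MBTPS2-sEDD-IFAP,
II,Keratitis ichthyosis deafness (KID) syndrome,GJB2-sEDD-KID,brownish_hyperkeratosis
II,Chanarin-Dorfman syndrome,ABHD5-sEDD,
II,Autosomal recessive keratitis-ichthyosis-deafness (KIDAR) syndrome,AP1B1-sEDD-KID,
III,Erythrokeratoderma variabilis (EKV),GJB3/GJB4-nEDD,scaly_erythema;PPK;no_systemic_manifestation
III,Keratitis ichthyosis deafness (KID) syndrome,GJB2-sEDD-KID,
III,Autosomal dominant lamellar ichthyosis,ASPRV1-nEDD,coarse_dark_scaling;lichenification_dorsum;plantar_hyperkeratosis
IV,Epidermolytic ichthyosis with KRT1 mutation,KRT1-nEDD,PPK
IV,Epidermolytic ichthyosis with KRT10 mutation,KRT10-nEDD,no_PPK
IV,Superficial epidermolytic ichthyosis,KRT2-nEDD,
IV,Annular epidermolytic ichthyosis,KRT10-nEDD-annular,
V,Congenital reticular ichthyosiform erythroderma (CRIE),KRT10-nEDD-CRIE,confetti_sparing
V,Ichthyosis hystrix of Curth-Macklin,KRT1-nEDD-spiny,spiny_hyperkeratosis
VI,Netherton syndrome,SPINK5-sEDD,erythroderma;infection_predisposition;food_allergies;hypereosinophilia;elevated_IgE;failure_to_thrive
VI,Peeling skin disease,CDSN-nEDD,erythema;skin_peeling;allergies;pruritus;hypereosinophilia;elevated_IgE;normal_growth
VI,Congenital hemidysplasia with ichthyosiform nevus and limb defects (CHILD) syndrome,NSDHL-sEDD-CHILD,
VI,Severe dermatitis multiple allergies metabolic wasting (SAM) syndrome,DSG1/DSP-sEDD,erythroderma;alopecia;allergies;hypereosinophilia;elevated_IgE;failure_to_thrive
VI,MALT1 deficiency,MALT1 deficiency,infection_predisposition;failure_to_thrive;periodontal_disease;enteropathy
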