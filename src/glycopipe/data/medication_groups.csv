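drug,group,drug_class
BENAZEPRIL,experimental,ACE inhibitor
ENALAPRIL,experimental,ACE inhibitor
FOSINOPRIL,experimental,ACE inhibitor
LISINOPRIL,experimental,ACE inhibitor
RAMIPRIL,experimental,ACE inhibitor
DICLOFENAC,experimental,NSAID
SULINDAC,experimental,NSAID
SILDENAFIL,experimental,PDE5 inhibitor
DOFETILIDE,experimental,antiarrhythmic
PROPAFENONE,experimental,antiarrhythmic
DABIGATRAN ETEXILATE,experimental,anticoagulant
LAMOTRIGINE,experimental,anticonvulsant
LEVETIRACETAM,experimental,anticonvulsant
OXCARBAZEPINE,experimental,anticonvulsant
PHENYTOIN,experimental,anticonvulsant
PREGABALIN,experimental,anticonvulsant
PRIMIDONE,experimental,anticonvulsant
TOPIRAMATE,experimental,anticonvulsant
MICONAZOLE,experimental,antifungal
ASPIRIN,experimental,antiplatelet
DIPYRIDAMOLE,experimental,antiplatelet
SALMON CALCITONIN,experimental,calcitonin
VERAPAMIL,experimental,calcium channel blocker
PENTOXIFYLLINE,experimental,hemorheologic
LIDOCAINE,experimental,local anesthetic
PRILOCAINE,experimental,local anesthetic
ISOSORBIDE,experimental,nitrate
ISOSORBIDE DINITRATE,experimental,nitrate
ATORVASTATIN,experimental,statin
FLUVASTATIN,experimental,statin
LOVASTATIN,experimental,statin
PRAVASTATIN,experimental,statin
ROSUVASTATIN,experimental,statin
SIMVASTATIN,experimental,statin
MINOXIDIL,experimental,vasodilator
SITAGLIPTIN,glucose_decreasing,DPP-4 inhibitor
LIRAGLUTIDE,glucose_decreasing,GLP-1 agonist
METFORMIN,glucose_decreasing,biguanide
INSULIN,glucose_decreasing,insulin
GLIMEPIRIDE,glucose_decreasing,sulfonylurea
GLIPIZIDE,glucose_decreasing,sulfonylurea
GLYBURIDE,glucose_decreasing,sulfonylurea
PIOGLITAZONE,glucose_decreasing,thiazolidinedione
CITALOPRAM,glucose_increasing,SSRI
FLUOXETINE,glucose_increasing,SSRI
PAROXETINE,glucose_increasing,SSRI
SERTRALINE,glucose_increasing,SSRI
OLANZAPINE,glucose_increasing,antipsychotic
QUETIAPINE,glucose_increasing,antipsychotic
RISPERIDONE,glucose_increasing,antipsychotic
ATENOLOL,glucose_increasing,beta blocker
BISOPROLOL,glucose_increasing,beta blocker
CARVEDILOL,glucose_increasing,beta blocker
METOPROLOL,glucose_increasing,beta blocker
NADOLOL,glucose_increasing,beta blocker
PROPRANOLOL,glucose_increasing,beta blocker
SOTALOL,glucose_increasing,beta blocker
EZETIMIBE,glucose_increasing,cholesterol absorption inhibitor
DEXAMETHASONE,glucose_increasing,corticosteroid
HYDROCORTISONE,glucose_increasing,corticosteroid
METHYLPREDNISOLONE,glucose_increasing,corticosteroid
PREDNISONE,glucose_increasing,corticosteroid
HYDROCHLOROTHIAZIDE,glucose_increasing,diuretic
CIPROFLOXACIN,glucose_increasing,fluoroquinolone
LEVOFLOXACIN,glucose_increasing,fluoroquinolone
MOXIFLOXACIN,glucose_increasing,fluoroquinolone
AMITRIPTYLINE,glucose_increasing,tricyclic antidepressant
DOXEPIN,glucose_increasing,tricyclic antidepressant
NORTRIPTYLINE,glucose_increasing,tricyclic antidepressant
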