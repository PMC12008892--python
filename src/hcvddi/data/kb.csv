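regimen,ingredient,pi_status,liverpool_status,drug_class
GLE/PIB,atazanavir,contraindicated,red,hiv antivirals
GLE/PIB,atorvastatin,contraindicated,red,lipid-lowering agents
GLE/PIB,aliskiren,none,red,renin inhibitors
GLE/PIB,amobarbital,none,red,antiepileptics/barbiturates
GLE/PIB,apalutamide,none,red,antiandrogens
GLE/PIB,bosentan,none,red,endothelin receptor antagonists
GLE/PIB,carbamazepine,none,red,antiepileptics/barbiturates
GLE/PIB,dabigatran,none,red,anticoagulants
GLE/PIB,darunavir/cobicistat/emtricitabine/tenofovir alafenamide,none,red,hiv antivirals
GLE/PIB,darunavir/cobicistat,none,red,hiv antivirals
GLE/PIB,desogestrel/ethinylestradiol,none,red,hormonal contraceptives
GLE/PIB,drospirenone/ethinyl estradiol,none,red,hormonal contraceptives
GLE/PIB,efavirenz,none,red,hiv antivirals
GLE/PIB,eltrombopag,none,red,thrombopoietin receptor agonists
GLE/PIB,ethinyl estradiol,none,red,hormonal contraceptives
GLE/PIB,etravirine,none,red,hiv antivirals
GLE/PIB,fosamprenavir,none,red,hiv antivirals
GLE/PIB,ledipasvir/sofosbuvir,none,red,hcv antivirals
GLE/PIB,levonorgestrel/ethinyl estradiol,none,red,hormonal contraceptives
GLE/PIB,lopinavir,none,red,hiv antivirals
GLE/PIB,nevirapine,none,red,hiv antivirals
GLE/PIB,nirmatrelvir/ritonavir,none,red,antivirals
GLE/PIB,norethisterone/ethinyl estradiol,none,red,hormonal contraceptives
GLE/PIB,norgestrel/ethinyl estradiol,none,red,hormonal contraceptives
GLE/PIB,phenobarbital,none,red,antiepileptics/barbiturates
GLE/PIB,phenytoin,none,red,antiepileptics/barbiturates
GLE/PIB,primidone,none,red,antiepileptics/barbiturates
GLE/PIB,rifabutin,none,red,antimycobacterials
GLE/PIB,rifampicin,contraindicated,red,antimycobacterials
GLE/PIB,ritonavir,none,red,hiv antivirals
GLE/PIB,simvastatin,none,red,lipid-lowering agents
GLE/PIB,sofosbuvir/velpatasvir,none,red,hcv antivirals
GLE/PIB,vinblastine,none,red,vinca alkaloids
GLE/PIB,vincristine,none,red,vinca alkaloids
GLE/PIB,quetiapine,none,amber,antipsychotics
GLE/PIB,aripiprazole,none,amber,antipsychotics
GLE/PIB,paliperidone,none,amber,antipsychotics
GLE/PIB,risperidone,none,yellow,antipsychotics
GLE/PIB,lurasidone,none,yellow,antipsychotics
GLE/PIB,domperidone,none,amber,gastrointestinal agents
GLE/PIB,sulfasalazine,none,amber,gastrointestinal agents
GLE/PIB,droperidol,none,amber,gastrointestinal agents
GLE/PIB,lansoprazole,none,yellow,gastrointestinal agents
GLE/PIB,esomeprazole,none,yellow,gastrointestinal agents
GLE/PIB,vonoprazan,none,yellow,gastrointestinal agents
GLE/PIB,famotidine,none,yellow,gastrointestinal agents
GLE/PIB,rabeprazole,none,yellow,gastrointestinal agents
GLE/PIB,omeprazole,none,yellow,gastrointestinal agents
GLE/PIB,lafutidine,none,yellow,gastrointestinal agents
GLE/PIB,loperamide,none,yellow,gastrointestinal agents
GLE/PIB,cimetidine,none,yellow,gastrointestinal agents
GLE/PIB,nizatidine,none,yellow,gastrointestinal agents
GLE/PIB,granisetron,none,yellow,gastrointestinal agents
GLE/PIB,roxatidine,none,yellow,gastrointestinal agents
GLE/PIB,rosuvastatin,caution,amber,lipid-lowering agents
GLE/PIB,pravastatin,caution,amber,lipid-lowering agents
GLE/PIB,ezetimibe,none,amber,lipid-lowering agents
GLE/PIB,pitavastatin,none,amber,lipid-lowering agents
GLE/PIB,fluvastatin,none,amber,lipid-lowering agents
SOF/VEL,risperidone,none,yellow,antipsychotics
SOF/VEL,esomeprazole,caution,amber,gastrointestinal agents
SOF/VEL,vonoprazan,none,amber,gastrointestinal agents
SOF/VEL,lansoprazole,caution,amber,gastrointestinal agents
SOF/VEL,rabeprazole,caution,amber,gastrointestinal agents
SOF/VEL,famotidine,none,amber,gastrointestinal agents
SOF/VEL,omeprazole,caution,amber,gastrointestinal agents
SOF/VEL,lafutidine,none,amber,gastrointestinal agents
SOF/VEL,cimetidine,none,amber,gastrointestinal agents
SOF/VEL,ranitidine hydrochloride,none,amber,gastrointestinal agents
SOF/VEL,atorvastatin,none,amber,lipid-lowering agents
SOF/VEL,rosuvastatin,caution,amber,lipid-lowering agents
SOF/VEL,fluvastatin,none,amber,lipid-lowering agents
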