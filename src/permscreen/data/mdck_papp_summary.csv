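drug_id,treatment_id,mean_papp_1e6_cm_s,sem_1e6_cm_s,n,atenolol_band
acyclovir,control,0.19,0.05,3,pass
acyclovir,lactose,0.05,0.02,3,pass
acyclovir,sorbitol,0.04,0.01,3,pass
acyclovir,SLS,0.52,0.01,3,pass
acyclovir,tween80,0.11,0.01,3,moderate
acyclovir,MCC,0.02,0.02,3,moderate
acyclovir,HPMC,0.07,0.01,3,pass
acyclovir,PVP,0.02,0.02,3,pass
acyclovir,CCS,0.03,0.01,3,pass
acyclovir,SSG,0.02,0.01,3,major
cimetidine,control,0.57,0.06,3,major
cimetidine,lactose,0.81,0.08,3,moderate
cimetidine,sorbitol,0.66,0.17,3,pass
cimetidine,SLS,0.73,0.16,3,moderate
cimetidine,tween80,2.20,0.37,3,moderate
cimetidine,MCC,0.44,0.11,3,moderate
cimetidine,HPMC,0.65,0.08,3,moderate
cimetidine,PVP,0.74,0.15,3,moderate
cimetidine,CCS,0.83,0.11,3,moderate
cimetidine,SSG,0.40,0.04,3,moderate
enalaprilat,control,0.06,0.01,3,pass
enalaprilat,lactose,0.15,0.05,3,pass
enalaprilat,sorbitol,0.13,0.04,3,pass
enalaprilat,SLS,0.27,0.06,3,pass
enalaprilat,tween80,0.21,0.11,3,moderate
enalaprilat,MCC,0.32,0.05,3,pass
enalaprilat,HPMC,0.18,0.02,3,pass
enalaprilat,PVP,0.07,0.03,3,pass
enalaprilat,CCS,0.19,0.09,3,pass
enalaprilat,SSG,0.30,0.02,3,pass
hydrochlorothiazide,control,0.56,0.18,3,pass
hydrochlorothiazide,lactose,0.77,0.33,3,pass
hydrochlorothiazide,sorbitol,0.37,0.03,3,pass
hydrochlorothiazide,SLS,1.03,0.20,3,pass
hydrochlorothiazide,tween80,0.78,0.09,3,moderate
hydrochlorothiazide,MCC,0.46,0.01,3,major
hydrochlorothiazide,HPMC,0.76,0.29,3,pass
hydrochlorothiazide,PVP,0.37,0.04,3,pass
hydrochlorothiazide,CCS,0.56,0.18,3,pass
hydrochlorothiazide,SSG,0.93,0.30,3,major
nadolol,control,0.38,0.06,3,pass
nadolol,lactose,0.44,0.02,3,pass
nadolol,sorbitol,0.75,0.20,3,pass
nadolol,SLS,3.46,0.33,3,moderate
nadolol,tween80,5.00,3.6,3,major
nadolol,MCC,0.26,0.09,3,moderate
nadolol,HPMC,0.42,0.04,3,major
nadolol,PVP,0.81,0.11,3,major
nadolol,CCS,0.52,0.06,3,major
nadolol,SSG,0.21,0.04,3,moderate
sulpiride,control,0.45,0.04,3,pass
sulpiride,lactose,0.72,0.23,3,major
sulpiride,sorbitol,0.56,0.01,3,pass
sulpiride,SLS,0.11,0.01,3,pass
sulpiride,tween80,0.08,0.01,3,major
sulpiride,MCC,0.40,0.08,3,moderate
sulpiride,HPMC,0.50,0.07,3,major
sulpiride,PVP,0.58,0.06,3,major
sulpiride,CCS,0.04,0.01,3,pass
sulpiride,SSG,0.08,0.01,3,moderate
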