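# AAL cerebral-cortex node list: 38 regions per hemisphere.
# Subcortical (hippocampus, parahippocampal, amygdala, caudate, putamen,
# pallidum, thalamus) and cerebellar regions excluded.
Precentral.L
Precentral.R
Frontal_Sup.L
Frontal_Sup.R
Frontal_Sup_Orb.L
Frontal_Sup_Orb.R
Frontal_Mid.L
Frontal_Mid.R
Frontal_Mid_Orb.L
Frontal_Mid_Orb.R
Frontal_Inf_Oper.L
Frontal_Inf_Oper.R
Frontal_Inf_Tri.L
Frontal_Inf_Tri.R
Frontal_Inf_Orb.L
Frontal_Inf_Orb.R
Rolandic_Oper.L
Rolandic_Oper.R
Supp_Motor_Area.L
Supp_Motor_Area.R
Olfactory.L
Olfactory.R
Frontal_Sup_Medial.L
Frontal_Sup_Medial.R
Frontal_Med_Orb.L
Frontal_Med_Orb.R
Rectus.L
Rectus.R
Insula.L
Insula.R
Cingulum_Ant.L
Cingulum_Ant.R
Cingulum_Mid.L
Cingulum_Mid.R
Cingulum_Post.L
Cingulum_Post.R
Calcarine.L
Calcarine.R
Cuneus.L
Cuneus.R
Lingual.L
Lingual.R
Occipital_Sup.L
Occipital_Sup.R
Occipital_Mid.L
Occipital_Mid.R
Occipital_Inf.L
Occipital_Inf.R
Fusiform.L
Fusiform.R
Postcentral.L
Postcentral.R
Parietal_Sup.L
Parietal_Sup.R
Parietal_Inf.L
Parietal_Inf.R
SupraMarginal.L
SupraMarginal.R
Angular.L
Angular.R
Precuneus.L
Precuneus.R
Paracentral_Lobule.L
Paracentral_Lobule.R
Heschl.L
Heschl.R
Temporal_Sup.L
Temporal_Sup.R
Temporal_Pole_Sup.L
Temporal_Pole_Sup.R
Temporal_Mid.L
Temporal_Mid.R
Temporal_Pole_Mid.L
Temporal_Pole_Mid.R
Temporal_Inf.L
Temporal_Inf.R
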