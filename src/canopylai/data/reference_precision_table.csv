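entity_id,canopy_class,species,mean_lai,r,rsd_r,R,rsd_R,labs_used,screening_note
sparse_high_q1,sparse_or_continuous_high_scaffold,Populus spp.,1.45,0.65,15.89,0.69,17.04,4,
sparse_high_q2,sparse_or_continuous_high_scaffold,Liriodendron tulipifera L.,3.78,2.57,24.26,2.57,24.26,4,
sparse_high_q3,sparse_or_continuous_high_scaffold,Fagus sylvatica L.,3.33,1.81,19.35,1.81,19.35,4,
sparse_high_q4,sparse_or_continuous_high_scaffold,Magnolia grandiflora L.,5.22,1.06,7.09,1.06,7.09,3,grubbs_outlier_lab_C
row_q1,plantation_row_low_scaffold,Populus spp.,1.48,0.41,9.99,0.43,10.32,3,cochran_outlier_lab_B
row_q2,plantation_row_low_scaffold,Robinia pseudoacacia L.,2.32,1.12,17.24,1.12,17.24,4,
row_q3,plantation_row_low_scaffold,Populus spp.,3.66,0.85,8.27,1.09,10.69,4,
row_q4,plantation_row_low_scaffold,Populus spp.,3.72,0.55,5.25,0.73,7.03,4,
sparse_medium_q1,sparse_medium_scaffold,Olea europaea L.,0.82,0.42,18.44,0.42,18.44,4,grubbs_stragglers_labs_B_C
sparse_medium_q2,sparse_medium_scaffold,Sorbus domestica L.,3.29,2.36,25.68,2.43,26.35,4,
sparse_medium_q3,sparse_medium_scaffold,Acer platanoides L.,5.11,1.66,11.58,1.66,11.58,4,
sparse_medium_q4,sparse_medium_scaffold,Fagus sylvatica L.,5.52,0.83,5.37,0.99,6.41,4,
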