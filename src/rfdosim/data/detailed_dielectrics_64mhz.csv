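tissue,label,sigma_S_per_m,eps_r,rho_kg_per_m3,source
Background,0,0.0,1.0,0.0,vacuum/air
Skin,1,0.44,92.2,1109.0,approx. Gabriel-database dry skin at 64 MHz
Fat,2,0.066,13.6,911.0,approx. Gabriel-database fat at 64 MHz
Muscle,3,0.69,72.2,1090.0,approx. Gabriel-database muscle at 64 MHz
Cortical_bone,4,0.059,16.7,1908.0,approx. Gabriel-database cortical bone at 64 MHz
Spongy_bone,5,0.16,30.9,1178.0,approx. Gabriel-database cancellous bone at 64 MHz
Skull,6,0.13,26.4,1800.0,approx. cortical/cancellous mixture at 64 MHz
Brain,7,0.55,85.0,1045.0,approx. grey/white-matter average at 64 MHz
Eyes,8,1.50,69.0,1005.0,approx. vitreous humour at 64 MHz
Lung,9,0.29,37.1,394.0,approx. inflated lung at 64 MHz
Heart,10,0.68,106.5,1081.0,approx. Gabriel-database heart muscle at 64 MHz
Liver,11,0.45,80.6,1079.0,approx. Gabriel-database liver at 64 MHz
Stomach,12,0.88,85.8,1088.0,approx. Gabriel-database stomach wall at 64 MHz
Kidney,13,0.74,118.6,1066.0,approx. Gabriel-database kidney at 64 MHz
Spleen,14,0.74,110.6,1089.0,approx. Gabriel-database spleen at 64 MHz
Limb_skin,15,0.44,92.2,1109.0,same as Skin; dedicated row for limb voxels
Limb_fat,16,0.066,13.6,911.0,same as Fat; dedicated row for limb voxels
Limb_muscle,17,0.69,72.2,1090.0,same as Muscle; dedicated row for limb voxels
Limb_bone,18,0.059,16.7,1908.0,same as Cortical_bone; dedicated row for limb voxels
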