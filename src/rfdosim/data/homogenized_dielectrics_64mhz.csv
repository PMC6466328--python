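tissue,label,sigma_S_per_m,eps_r,rho_kg_per_m3,source
Background,0,0.0,1.0,0.0,vacuum/air
Eyes,1,1.24,70.96,1050.0,mass-weighted homogenized value at 64 MHz; density approx. (IT'IS-style)
Brain,2,0.69,72.35,1045.0,mass-weighted homogenized value at 64 MHz; density approx. (IT'IS-style)
Cartilage,3,0.60,66.76,1100.0,mass-weighted homogenized value at 64 MHz; density approx. (IT'IS-style)
skull,4,0.13,26.38,1800.0,mass-weighted homogenized value at 64 MHz; density approx. (IT'IS-style)
Muscle,5,0.69,72.24,1090.0,mass-weighted homogenized value at 64 MHz; density approx. (IT'IS-style)
Stomach,6,0.88,85.81,1088.0,mass-weighted homogenized value at 64 MHz; density approx. (IT'IS-style)
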