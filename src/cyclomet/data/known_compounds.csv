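name,compound_class,rt_min,ion_formula,measured_mz,calc_mz,ppm_printed
Griseofulvin,PKS,11.42,C17H18ClO6,353.0793,353.0786,-1.98
Dechlorogriseofulvin,PKS,10.01,C17H19O6,319.1173,319.1176,0.94
Cytochalasin D,PKS-NRPS,11.81,C30H38NO6,508.2687,508.2694,1.38
Zygosporin E,PKS-NRPS,13.94,C30H38NO5,492.2742,492.2744,0.41
Epoxycytochalasin D,PKS-NRPS,10.87,C30H38NO7,524.2651,524.2661,1.91
Hirsutatin A,NRPS,15.85,C34H53N4O10,677.3741,677.3756,2.21
Piliformic acid,PKS,10.84,C11H18O4Na,237.1094,237.1097,1.27
"2,3-dihydro-2,4-dimethylbenzofuran-7-carboxylic acid",PKS,11.15,C11H13O3,193.0857,193.0859,1.04
Cyclic pentapeptide 1,NRPS,16.20,C32H50N5O5,584.3816,584.3806,-1.71
Xylarotide A,NRPS,15.97,C29H52N5O5,550.3973,550.3963,-1.82
Cyclic pentapeptide 2,NRPS,14.28,C28H50N5O5,536.3819,536.3806,-2.42
Ellisiiamide A,NRPS,14.76,C30H46N5O5,556.3501,556.3493,-1.44
Ellisiiamide B,NRPS,15.19,C31H48N5O5,570.3656,570.3650,-1.05
Ellisiiamide C,NRPS,17.04,C33H52N5O5,598.3968,598.3963,-0.84
Ellisiiamide D,NRPS,14.47,C27H48N5O5,522.3662,522.3650,-2.30
Ellisiiamide E,NRPS,16.89,C30H54N5O5,564.4132,564.4119,-2.30
Ellisiiamide F,NRPS,14.11,C31H48N5O6,586.3616,586.3599,-1.72
Ellisiiamide G,NRPS,14.00,C32H50N5O6,600.3768,600.3756,-2.00
Ellisiiamide H,NRPS,14.89,C33H52N5O6,614.3936,614.3912,-2.41
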