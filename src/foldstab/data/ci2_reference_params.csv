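variant,t_m,t_m_se,dh_m,dh_m_se,dcp,dcp_se,m,m_se,dg_f,dg_f_se,d50,d50_se,ddg_common_m,ddg_common_m_se,i57a_library
I30K/I57A,327.4,3.1,-99,11,-0.4,0.8,8.8,1.8,-8.2,0.6,0.9,0.2,,,1
A16D/P33Q/G35E/V38M/Q59K,333.3,1.9,-134,9,-2.6,0.3,5.4,0.5,-9.1,0.6,1.7,0.2,,,0
K18E/P33Q/V47D,336.0,1.7,-147,10,-2.9,0.1,4.3,0.2,-10.1,1.0,2.3,0.2,,,0
I44N/I57A,339.0,2.4,-163,28,-2.6,0.4,7.4,1.5,-13.0,2.8,1.8,0.5,,,1
A27V/D52G,341.7,1.0,-211,19,-3.6,0.3,6.0,0.8,-16.4,1.5,2.7,0.4,,,0
E41G/F50L/I57A,331.6,0.5,-191,3,-1.5,0.1,11.5,0.2,-16.6,0.4,1.4,0.0,,,1
A16T/N56I,339.4,0.6,-227,19,-4.1,0.3,7.0,0.4,-17.0,1.5,2.4,0.2,,,0
V31D/I57A,344.7,0.5,-222,0,-3.7,0.0,7.0,0.0,-17.7,0.1,2.5,0.0,,,1
I57A,333.1,0.5,-269,14,-5.4,0.5,11.6,0.6,-17.9,0.6,1.5,0.1,,,1
G10E/T39S,339.7,0.7,-238,16,-4.0,0.7,8.5,0.5,-18.4,0.4,2.2,0.1,,,0
M40T/R48S/I57V,344.3,0.3,-235,9,-3.8,0.2,7.1,0.1,-19.1,0.4,2.7,0.1,,,1
G35W/A58V,336.8,0.1,-281,19,-5.7,0.5,6.9,0.2,-19.1,0.9,2.8,0.1,,,0
E4G,341.5,0.1,-259,7,-4.0,0.2,7.3,0.1,-21.4,0.3,2.9,0.1,,,0
L32Q/I57S,348.1,0.6,-275,5,-4.4,0.0,6.1,0.2,-22.9,0.7,3.8,0.2,,,0
V13E,343.1,0.2,-280,23,-4.1,0.5,9.6,0.6,-24.0,1.6,2.5,0.2,,,0
E15G/M40T/R48C/I57V,347.6,0.1,-281,8,-4.1,0.1,8.3,0.2,-24.9,0.7,3.0,0.1,,,1
V38E/I57V,348.8,0.3,-295,16,-4.4,0.3,8.9,0.5,-25.8,1.2,2.9,0.2,,,1
T39A/I57N,343.5,0.2,-312,0,-4.7,0.0,10.6,0.1,-26.4,0.1,2.5,0.0,,,0
L49I,350.3,0.2,-322,8,-4.6,0.1,8.7,0.2,-28.9,0.8,3.3,0.1,3.4,0.1,0
V34E/D45Y,344.3,0.0,-363,7,-6.0,0.2,8.4,0.2,-29.2,0.5,3.5,0.1,,,0
wild-type,352.3,0.2,-322,11,-4.3,0.2,8.2,0.1,-30.5,0.8,3.7,0.1,0.0,,0
P33L,354.1,0.5,-330,43,-4.2,0.7,8.3,0.8,-32.5,3.5,3.9,0.6,,,0
L49I/I57V,356.2,0.3,-332,13,-4.2,0.2,7.9,0.4,-32.9,1.3,4.2,0.3,-3.8,0.1,1
I57V,354.5,0.2,-349,12,-4.7,0.2,8.3,0.2,-33.3,0.9,4.0,0.1,-2.2,0.1,1
D55G/I57V,361.6,0.3,-364,13,-4.3,0.2,8.5,0.2,-38.1,0.8,4.5,0.1,-6.5,0.2,1
D55G,361.1,0.1,-378,10,-4.7,0.1,8.5,0.2,-38.4,1.0,4.5,0.2,-6.9,0.3,0
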