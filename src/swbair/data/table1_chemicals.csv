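name,cas,abbrev,class,mw,bp_exp_c,bp_test_c,bp_opera_c,log_koa,vp_mmhg,exposure_ng_per_l
Dichloromethane,75-09-2,DCM,VOC,85,40,44.4,40.0,2.29,4.33E+02,2470
Acrolein,107-02-8,ACO,VOC,53,52,52.4,52.7,2.11,2.72E+02,625
Acrylonitrile,107-13-1,ACY,VOC,53,77,107,77.4,2.44,1.07E+02,4360
Methyl ethyl ketone,78-93-3,MEK,VOC,72,80,85.9,79.3,2.73,9.06E+01,4540
Benzene,71-43-2,BEN,VOC,78,80,96.2,80.1,2.83,9.47E+01,1600
Toluene,108-88-3,TOL,VOC,92,111,112,111,3.49,2.83E+01,3800
"1,1,2-Trichloroethane",79-00-5,112-TCA,VOC,133,114,113,114,3.35,2.35E+01,1790
4-Methyl-2-pentanone,108-10-1,MIBK,VOC,100,117,119,116,3.58,1.97E+01,4620
"1,1,2,2-Tetrachloroethane",79-34-5,1122-TCA,VOC,168,147,132,147,3.46,4.67E+00,3100
p-Xylene,106-42-3,XYL,VOC,106,138,141,141,3.84,8.84E+00,166
"1,2,4-Trimethylbenzene",95-63-6,"1,2,4-TMB",VOC,120,169,178,170,4.54,2.10E+00,65.8
"1,3-Dichlorobenzene",541-73-1,"1,3-DCB",VOC,147,173,182,173,4.16,2.15E+00,182
Undecane,1120-21-4,UDEC,VOC,156,196,190,196,5.01,4.12E-01,42.7
"1,2,4-Trichlorobenzene",120-82-1,"1,2,4-TCB",VOC,181,214,226,213,4.96,4.59E-01,74.8
"2,4-Dinitrotoluene",121-14-2,"2,4-DNT",SVOC,182,300,305,300,5.08,1.48E-04,4.46;3.76
Hexachlorobenzene,118-74-1,HCB,SVOC,285,325,293,325,7.37,1.82E-05,117;0.590
Tris(chloroethyl)phosphate,115-96-8,TCEP,SVOC,285,330,295,330,8.41,6.09E-02,2.61
Phenanthrene,85-01-8,PHE,SVOC,178,340,341,340,7.55,1.12E-04,1.50
Chlorpyrifos,2921-88-2,CLPYF,SVOC,351,,,364,10.6,2.03E-05,3.49
Pyrene,129-00-0,PYR,SVOC,202,404,415,394,8.86,4.48E-06,0.307
Fluoranthene,206-44-0,FLA,SVOC,202,384,378,394,8.86,9.08E-06,0.506
Permethrin,52645-53-1,PERN,SVOC,391,,412,401,11.7,2.19E-08,0.162
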