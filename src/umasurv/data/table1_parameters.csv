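cell_line,tumor,d0_gy,n,dose_per_fraction_gy,fractions,alpha_printed_gy_inv,alpha_beta_printed_gy,eqd2_printed_gy,lq_eqd2_printed_gy,clinical_alpha_beta_gy,group,ref_d0_gy,ref_n
Hypoxic Bell,Melanoma,6.50,2.0,20.0,1,1.7E-01,3.3E+02,29.3,50.0,10,srs_20x1,,
Oxic Bell,Melanoma,5.50,1.4,20.0,1,1.9E-01,1.1E+03,24.3,50.0,10,srs_20x1,,
"Bell,MelH",Melanoma,1.68,3.5,20.0,1,6.0E-01,2.1E+05,41.9,50.0,10,srs_20x1,,
OMM-1,Metastatic Melanoma,1.00,3.3,20.0,1,1.0E+00,4.2E+08,34.9,50.0,10,srs_20x1,,
OMM 2-2,Metastatic Melanoma,0.81,4.4,20.0,1,1.2E+00,2.5E+10,37.4,50.0,10,srs_20x1,,
OMM 2-3,Metastatic Melanoma,1.23,3.0,20.0,1,8.1E-01,1.4E+07,35.3,50.0,10,srs_20x1,,
OMM 2-6,Metastatic Melanoma,1.11,4.2,20.0,1,9.0E-01,4.6E+07,41.9,50.0,10,srs_20x1,,
U373MG,Glioblastoma,1.73,4.2,20.0,1,5.8E-01,1.1E+05,48.5,50.0,10,srs_20x1,,
SW1573,Lung SCC,1.00,11.7,10.0,5,1.0E+00,4.1E+03,173.1,90.0,8,lung_10x5,,
In-vivo HX147,LCLC,3.00,3.2,10.0,5,3.8E-01,1.0E+02,86.6,90.0,8,lung_10x5,,
In-vivo HX149M,Variant SCLC,2.27,4.0,10.0,5,4.9E-01,1.5E+02,101.0,90.0,8,lung_10x5,,
In-vivo HX144,Lung AdC,2.20,4.0,10.0,5,5.0E-01,1.6E+02,101.2,90.0,8,lung_10x5,,
In-vivo HC12,Classical SCLC,1.70,4.5,10.0,5,6.2E-01,3.7E+02,108.5,90.0,8,lung_10x5,,
NHIK 3025 n=1,Cervical AdC,2.80,1.0,7.0,5,3.6E-01,,35.0,49.6,10,hdrb_7x5,,
NHIK 3025 n=58,Cervical AdC,2.70,58.0,7.0,5,2.2E-01,2.1E+01,103.1,49.6,10,hdrb_7x5,,
NHIK 3025 40Gy Med,Cervical AdC,2.71,2.8,7.0,5,4.3E-01,5.9E+01,51.1,49.6,10,hdrb_7x5,,
RL95-2,Primary EC,1.11,1.5,7.0,5,9.1E-01,2.4E+03,40.0,49.6,10,hdrb_7x5,,
KLE,Primary EC,1.12,2.6,7.0,5,9.1E-01,7.4E+02,49.6,49.6,10,hdrb_7x5,,
UM-EC-1,Primary EC,1.83,2.1,7.0,5,5.8E-01,1.7E+02,46.7,49.6,10,hdrb_7x5,,
UT-EC-1,Primary EC,2.40,1.5,7.0,5,4.4E-01,2.0E+02,40.6,49.6,10,hdrb_7x5,,
UM-EC-2,Metastatic EC,1.45,0.9,1.2,40,6.9E-01,-6.1E+01,48.7,52.8,10,hyper_1p2,,
UT-EC-2,Metastatic EC,0.75,0.5,1.2,40,1.2E+00,-1.1E+01,52.6,52.8,10,hyper_1p2,,
SKX,BOT SCC,2.55,0.2,1.2,60,4.2E-01,-2.7E+00,85.8,79.2,10,hyper_1p2,,
DaFu,H&N SCC,1.58,2.7,3.0,18,7.0E-01,2.2E+01,61.4,47.3,10,other,,
Hypoxic HT29,Colorectal AdC,3.24,15.0,5.0,5,1.7E-01,1.9E+01,39.6,32.5,8,other,,
Oxic HT29,Colorectal AdC,2.90,4.0,5.0,5,3.6E-01,2.7E+01,34.6,32.5,8,other,,
Plates HT29,Colorectal AdC,0.97,14.0,5.0,5,1.3E+00,3.8E+01,64.9,32.5,8,other,,
DU145,Prostate AdC,2.20,2.8,7.4,5,5.1E-01,9.0E+01,56.4,77.0,3,other,,
CP3,Prostate AdC,1.08,20.0,7.4,5,1.0E+00,1.2E+02,162.9,77.0,3,other,,
MDA-MB-231 gamma,Breast Cancer,1.49,3.8,2.66,16,7.2E-01,1.5E+01,48.1,44.9,10,other,,
MDA-MB-231 alpha,Breast Cancer,0.80,1.0,2.50,5,1.3E+00,,56.2,13.0,10,other,1.49,3.8
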