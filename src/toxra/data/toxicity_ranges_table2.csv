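cas,chemical,taxon,n,min_mg_L,max_mg_L
30560-19-1,Acephate,fish,12,1.46e-3,3.08e3
30560-19-1,Acephate,crustacean,7,3.50e-1,2.35e3
30560-19-1,Acephate,insect,9,1.14e-1,6.50e2
30560-19-1,Acephate,amphibian,2,6.43e3,8.82e3
62-73-7,Dichlorvos,fish,38,6.41e-3,1.67e2
62-73-7,Dichlorvos,crustacean,25,1.30e-4,1.29e2
62-73-7,Dichlorvos,insect,24,1.00e-4,2.38e2
62-73-7,Dichlorvos,amphibian,5,7.80e-1,7.89e1
10265-92-6,Methamidophos,fish,8,5.36e1,1.12e2
10265-92-6,Methamidophos,crustacean,4,1.61e-6,1.46e0
10265-92-6,Methamidophos,amphibian,1,2.72e1,2.72e1
7786-34-7,Mevinphos,fish,12,2.23e-2,4.00e1
7786-34-7,Mevinphos,crustacean,9,9.50e-4,1.30e-1
7786-34-7,Mevinphos,insect,1,4.95e-3,4.95e-3
22224-92-6,Nemacur,fish,3,1.75e-2,1.40e-1
22224-92-6,Nemacur,crustacean,6,2.65e-3,1.50e-1
41198-08-7,Profenofos,fish,17,2.55e-3,2.02e0
41198-08-7,Profenofos,crustacean,11,4.10e-5,7.71e0
41198-08-7,Profenofos,insect,6,1.18e-2,3.70e0
41198-08-7,Profenofos,amphibian,1,5.80e-1,5.80e-1
2032-59-9,Aminocarb,fish,12,5.24e-1,1.00e2
2032-59-9,Aminocarb,crustacean,8,1.20e-2,3.27e1
2032-59-9,Aminocarb,insect,7,2.25e-2,2.86e0
63-25-2,Carbaryl,fish,60,6.93e-7,1.08e2
63-25-2,Carbaryl,crustacean,41,3.75e-3,9.65e0
63-25-2,Carbaryl,insect,42,6.94e-7,4.79e0
63-25-2,Carbaryl,amphibian,17,1.64e0,5.53e1
1563-66-2,Carbofuran,fish,28,4.23e-2,7.90e0
1563-66-2,Carbofuran,crustacean,15,3.32e-4,2.70e0
1563-66-2,Carbofuran,insect,8,1.19e-4,1.59e0
1563-66-2,Carbofuran,amphibian,3,1.12e1,1.13e2
114-26-1,Propoxur,fish,12,1.30e0,4.25e1
114-26-1,Propoxur,crustacean,7,1.50e-2,1.43e0
114-26-1,Propoxur,insect,22,1.80e-2,8.00e0
116-06-3,Aldicarb,fish,9,6.56e-2,4.50e1
116-06-3,Aldicarb,crustacean,16,1.20e-2,1.73e1
116-06-3,Aldicarb,insect,5,2.00e-2,2.80e-1
16752-77-5,Methomyl,fish,14,3.40e-1,5.25e0
16752-77-5,Methomyl,crustacean,19,6.40e-3,7.20e0
16752-77-5,Methomyl,insect,4,6.43e-2,8.79e-1
16752-77-5,Methomyl,amphibian,3,5.55e1,6.16e2
23135-22-0,Oxamyl,fish,6,2.60e0,2.75e1
23135-22-0,Oxamyl,crustacean,4,2.20e-1,2.30e1
2921-88-2,Chlorpyrifos,fish,40,5.80e-4,5.98e-1
2921-88-2,Chlorpyrifos,crustacean,47,7.28e-11,4.57e-1
2921-88-2,Chlorpyrifos,insect,85,5.00e-5,3.80e-1
2921-88-2,Chlorpyrifos,amphibian,6,1.90e-2,5.62e-1
333-41-5,Diazinon,fish,53,7.00e-5,4.00e1
333-41-5,Diazinon,crustacean,20,3.87e-4,1.25e0
333-41-5,Diazinon,insect,23,5.67e-4,2.20e-1
333-41-5,Diazinon,amphibian,5,3.43e0,1.48e1
2104-64-5,EPN,fish,11,1.81e-2,4.20e-1
2104-64-5,EPN,crustacean,6,2.90e-4,4.38e-2
2104-64-5,EPN,insect,2,1.10e-3,7.40e-3
115-90-2,Fensulfothion,fish,3,7.20e-2,4.31e1
115-90-2,Fensulfothion,crustacean,2,1.00e-2,5.07e-2
55-38-9,Fenthion,fish,21,4.53e-1,3.10e0
55-38-9,Fenthion,crustacean,16,1.52e-4,1.80e0
55-38-9,Fenthion,insect,57,5.00e-4,1.10e0
55-38-9,Fenthion,amphibian,1,9.40e-4,9.40e-4
298-00-0,Methyl parathion,fish,42,5.00e-3,1.90e1
298-00-0,Methyl parathion,crustacean,28,2.05e-4,4.00e0
298-00-0,Methyl parathion,insect,12,5.40e-4,2.74e-1
298-00-0,Methyl parathion,amphibian,4,3.70e0,9.59e0
86-50-0,Azinphos-methyl,fish,26,3.60e-4,4.06e0
86-50-0,Azinphos-methyl,crustacean,10,1.61e-4,1.38e1
86-50-0,Azinphos-methyl,insect,6,3.70e-4,8.85e-2
60-51-5,Dimethoate,fish,26,1.30e-1,4.20e1
60-51-5,Dimethoate,crustacean,14,2.00e-3,1.50e1
60-51-5,Dimethoate,insect,13,1.29e-3,9.60e0
60-51-5,Dimethoate,amphibian,5,7.82e-3,3.75e1
298-04-4,Disulfoton,fish,10,3.70e-2,7.20e0
298-04-4,Disulfoton,crustacean,3,3.90e-3,1.00e-1
298-04-4,Disulfoton,insect,1,5.00e-3,5.00e-3
944-22-9,Dyfonate,fish,5,1.60e-2,1.09e0
944-22-9,Dyfonate,crustacean,2,4.90e-4,2.70e-3
944-22-9,Dyfonate,insect,2,3.90e-2,5.40e-2
121-75-5,Malathion,fish,72,1.95e-2,1.70e1
121-75-5,Malathion,crustacean,46,9.70e-5,8.15e1
121-75-5,Malathion,insect,67,1.00e-3,2.69e1
121-75-5,Malathion,amphibian,9,5.90e-4,3.32e1
13071-79-9,Terbufos,fish,8,2.90e-3,1.31e-1
13071-79-9,Terbufos,crustacean,5,2.97e-4,1.00e-2
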