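name,cas,molecular_weight,log_kow,water_solubility_mg_L,moa,functional_group,subgroup,verhaar_class
Acephate,30560-19-1,183.16,-0.85,818.00,AChE_inhibition,ester_phosphate,,5
Dichlorvos,62-73-7,220.97,1.43,8.00,AChE_inhibition,ester_phosphate,,5
Methamidophos,10265-92-6,141.13,-0.80,1000.00,AChE_inhibition,ester_phosphate,,5
Mevinphos,7786-34-7,224.15,0.13,600.00,AChE_inhibition,ester_phosphate,,5
Nemacur,22224-92-6,303.36,3.23,0.33,AChE_inhibition,ester_phosphate,,5
Profenofos,41198-08-7,373.63,4.68,0.03,AChE_inhibition,ester_phosphate,,5
Aminocarb,2032-59-9,208.26,1.90,0.92,AChE_inhibition,carbamate,Carbamate Esters Phenyl,4
Carbaryl,63-25-2,201.22,2.36,0.11,AChE_inhibition,carbamate,Carbamate Esters Phenyl,4
Carbofuran,1563-66-2,221.25,2.32,0.32,AChE_inhibition,carbamate,Carbamate Esters Phenyl,4
Propoxur,114-26-1,209.24,1.52,1.86,AChE_inhibition,carbamate,Carbamate Esters Phenyl,4
Aldicarb,116-06-3,190.26,1.13,6.03,AChE_inhibition,carbamate,Oxime Carbamate Ester,4
Methomyl,16752-77-5,162.21,0.60,58.00,AChE_inhibition,carbamate,Oxime Carbamate Ester,4
Oxamyl,23135-22-0,219.26,-0.47,280.00,AChE_inhibition,carbamate,Oxime Carbamate Ester,4
Chlorpyrifos,2921-88-2,350.59,4.96,0.001,AChE_inhibition,thiophosphate,Mono,4
Diazinon,333-41-5,304.35,3.81,0.04,AChE_inhibition,thiophosphate,Mono,4
EPN,2104-64-5,323.31,4.78,0.003,AChE_inhibition,thiophosphate,Mono,4
Fensulfothion,115-90-2,308.35,2.23,2.00,AChE_inhibition,thiophosphate,Mono,4
Fenthion,55-38-9,278.32,4.09,0.01,AChE_inhibition,thiophosphate,Mono,4
Methyl parathion,298-00-0,263.21,2.86,0.04,AChE_inhibition,thiophosphate,Mono,4
Azinphos-methyl,86-50-0,317.32,2.75,0.02,AChE_inhibition,thiophosphate,Di,4
Dimethoate,60-51-5,229.25,0.78,23.30,AChE_inhibition,thiophosphate,Di,4
Disulfoton,298-04-4,274.39,4.02,0.02,AChE_inhibition,thiophosphate,Di,4
Dyfonate,944-22-9,246.32,3.94,0.02,AChE_inhibition,thiophosphate,Di,4
Malathion,121-75-5,330.35,2.36,0.14,AChE_inhibition,thiophosphate,Di,4
Terbufos,13071-79-9,288.42,4.48,0.01,AChE_inhibition,thiophosphate,Di,4
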