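name	cen_motif	tel_motif	submotifs	3DL3	2DS2	2DL2	2DL3	2DL5	2DS35	2DP1	2DL1	3DP1	2DL4	3DL1	3DS1	2DS1	2DS4	3DL2	2DL1/S1	2DP1/L1	3DL1/L2	2DS2/S3	3DL2p	frequency
cA01|tA01	cA01	tA01	.	1	0	0	1	0	0	1	1	1	1	1	0	0	1	1	0	0	0	0	0	0.5302267903811504
cA01|tB01	cA01	tB01	.	1	0	0	1	1	1	1	1	1	1	0	1	1	0	1	0	0	0	0	0	0.13950344317359584
cB01|tA01	cB01	tA01	.	1	1	1	0	1	1	1	1	1	1	1	0	0	1	1	0	0	0	0	0	0.09150036499181664
cB01|tB01	cB01	tB01	.	1	1	1	0	2	2	1	1	1	1	0	1	1	0	1	0	0	0	0	0	0.02407387970499076
cB02|tA01	cB02	tA01	.	1	1	1	0	0	0	0	0	1	1	1	0	0	1	1	0	0	0	0	0	0.11772254751328097
cB02|tB01	cB02	tB01	.	1	1	1	0	1	1	0	0	1	1	0	1	1	0	1	0	0	0	0	0	0.0309729742351656
cB03|tA01	cB03	tA01	.	1	0	0	1	1	1	1	1	1	1	1	0	0	1	1	0	0	0	0	0	0.0024000000000000007
cB01|tA01-del3	cB01	tA01	del3	1	0	1	0	1	1	1	1	1	1	1	0	0	1	1	0	0	0	0	0	0.0013500000000000005
cB02|tA01-del3	cB02	tA01	del3	1	0	1	0	0	0	0	0	1	1	1	0	0	1	1	0	0	0	0	0	0.0013500000000000005
cB01|tA01-del4	cB01	tA01	del4	1	1	0	0	1	1	1	1	1	1	1	0	0	1	1	0	0	0	0	0	0.00020000000000000006
cB01|tA01-del9	cB01	tA01	del9	1	1	1	0	0	0	0	1	1	1	1	0	0	1	1	0	0	0	0	0	0.00020000000000000006
cB01|tA01-del10	cB01	tA01	del10	1	0	0	0	0	0	1	1	1	1	1	0	0	1	1	0	0	0	1	0	0.0019000000000000006
cA01|tA01-hybd1	cA01	tA01	hybd1	1	0	0	1	0	0	1	1	1	1	0	0	0	0	0	0	0	1	0	0	0.0013000000000000004
cB01|tA01-hybd1	cB01	tA01	hybd1	1	1	1	0	1	1	1	1	1	1	0	0	0	0	0	0	0	1	0	0	0.0013000000000000004
cB02|tA01-hybd1	cB02	tA01	hybd1	1	1	1	0	0	0	0	0	1	1	0	0	0	0	0	0	0	1	0	0	0.0013000000000000004
cA01|tA01-del5	cA01	tA01	del5	1	0	0	1	0	0	1	1	0	0	0	0	0	1	1	0	0	0	0	0	0.0005500000000000002
cB01|tA01-del5	cB01	tA01	del5	1	1	1	0	1	1	1	1	0	0	0	0	0	1	1	0	0	0	0	0	0.0005500000000000002
cA01|tB01-del6	cA01	tB01	del6	1	0	0	1	1	1	1	1	0	0	0	0	1	0	1	0	0	0	0	0	0.011850000000000005
cB02|tB01-del6	cB02	tB01	del6	1	1	1	0	1	1	0	0	0	0	0	0	1	0	1	0	0	0	0	0	0.011850000000000005
cA01|tB01-del7-3DL2p	cA01	tB01	del7	1	0	0	1	0	0	1	0	0	0	0	0	0	0	0	1	0	0	0	1	0.004214545454545456
cA01|tB01-del7	cA01	tB01	del7	1	0	0	1	0	0	1	0	0	0	0	0	0	0	1	1	0	0	0	0	0.00044363636363636377
cA01|tB01-del8	cA01	tB01	del8	1	0	0	1	0	0	1	0	0	0	0	0	0	0	1	1	0	0	0	0	0.00022181818181818188
cB01|tB01-del7	cB01	tB01	del7	1	1	1	0	1	1	1	0	0	0	0	0	0	0	1	1	0	0	0	0	0.0012200000000000004
cA01|tA01-ins3	cA01	tA01	ins3	1	0	0	1	0	0	1	1	2	2	2	0	0	1	1	0	0	0	0	0	0.00040000000000000013
cB02|tA01-ins3	cB02	tA01	ins3	1	1	1	0	0	0	0	0	2	2	2	0	0	1	1	0	0	0	0	0	0.00040000000000000013
cA01|tB01-ins3	cA01	tB01	ins3	1	0	0	1	1	1	1	1	2	2	1	1	1	0	1	0	0	0	0	0	0.00040000000000000013
cB01|tB01-ins3	cB01	tB01	ins3	1	1	1	0	2	2	1	1	2	2	1	1	1	0	1	0	0	0	0	0	0.00040000000000000013
cA01|tA01-ins4	cA01	tA01	ins4	1	0	0	1	0	0	1	1	2	2	1	1	0	1	1	0	0	0	0	0	0.0025250000000000008
cB01|tA01-ins4	cB01	tA01	ins4	1	1	1	0	1	1	1	1	2	2	1	1	0	1	1	0	0	0	0	0	0.0025250000000000008
cB02|tA01-ins4	cB02	tA01	ins4	1	1	1	0	0	0	0	0	2	2	1	1	0	1	1	0	0	0	0	0	0.0025250000000000008
cB01|tB01-ins4	cB01	tB01	ins4	1	1	1	0	2	2	1	1	2	2	0	2	1	0	1	0	0	0	0	0	0.0025250000000000008
cA01|tA01-ins5	cA01	tA01	ins5	1	0	0	1	1	1	1	1	2	2	1	1	0	1	1	0	1	0	0	0	0.002625000000000001
cB01|tA01-ins5	cB01	tA01	ins5	1	1	1	0	2	2	1	1	2	2	1	1	0	1	1	0	1	0	0	0	0.002625000000000001
cB02|tA01-ins5	cB02	tA01	ins5	1	1	1	0	1	1	0	0	2	2	1	1	0	1	1	0	1	0	0	0	0.002625000000000001
cB03|tA01-ins5	cB03	tA01	ins5	1	0	0	1	2	2	1	1	2	2	1	1	0	1	1	0	1	0	0	0	0.002625000000000001
cB01|tA01-del3-hybd1	cB01	tA01	del3,hybd1	1	0	1	0	1	1	1	1	1	1	0	0	0	0	0	0	0	1	0	0	0.0008000000000000003
cB02|tB01-del3-del6	cB02	tB01	del3,del6	1	0	1	0	1	1	0	0	0	0	0	0	1	0	1	0	0	0	0	0	0.0008000000000000003
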