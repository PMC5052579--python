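area,state,site,phytopigment_ug_g,phytopigment_sd,protein_mg_g,protein_sd,carbohydrate_mg_g,carbohydrate_sd,lipid_mg_g,lipid_sd,bpc_mg_g,bpc_sd,pct_phyto_bpc,pct_protein_bpc,prt_cho
Minorca,Barren,Site1,523.8,116.3,10.2,2.0,18.1,1.9,0.6,0.0,12.7,1.8,44.2,39.5,0.6
Minorca,Barren,Site2,69.3,14.9,2.1,0.2,3.5,0.6,0.3,0.0,2.7,0.2,27.9,37.8,0.6
Minorca,Meadow,Site1,3401.6,555.8,6.3,0.3,34.4,5.5,3.3,0.3,19.4,2.3,,16.0,0.2
Minorca,Meadow,Site2,2300.0,892.9,3.0,0.5,6.2,0.4,0.4,0.0,4.3,0.4,,34.6,0.5
Sardinia,Barren,Site1,251.6,11.2,4.4,0.4,35.3,3.2,2.8,0.3,18.4,1.7,10.7,11.7,0.1
Sardinia,Barren,Site2,157.6,30.8,2.2,0.3,9.0,1.4,4.7,0.5,8.3,0.4,18.2,13.3,0.2
Sardinia,Meadow,Site1,380.0,0.5,12.9,0.8,15.0,2.0,2.8,0.5,14.4,0.8,32.6,43.8,0.9
Sardinia,Meadow,Site2,260.5,28.8,13.3,1.8,5.8,1.6,2.6,0.1,10.8,1.5,26.3,60.6,2.3
Tuscany,Barren,Site1,103.4,34.5,2.6,0.1,24.8,0.6,0.3,0.0,11.5,0.3,13.9,11.2,0.1
Tuscany,Barren,Site2,254.1,8.9,4.3,0.4,12.4,0.8,1.8,0.3,8.4,0.3,45.8,25.2,0.3
Tuscany,Meadow,Site1,801.5,448.6,12.9,1.6,11.2,0.3,1.3,0.3,11.8,0.9,96.2,53.8,1.2
Tuscany,Meadow,Site2,618.5,91.9,5.6,0.2,7.3,2.0,2.5,0.3,7.5,1.0,,36.7,0.8
Sicily,Barren,Site1,99.1,3.0,4.2,0.4,9.5,1.0,3.3,0.2,8.3,0.2,9.3,24.9,0.4
Sicily,Barren,Site2,35.0,1.0,3.4,0.2,1.1,0.1,0.8,0.1,2.7,0.2,12.7,61.6,3.2
Sicily,Meadow,Site1,257.5,15.5,23.6,2.8,20.5,1.6,5.4,0.2,23.8,0.7,5.8,48.5,1.2
Sicily,Meadow,Site2,168.8,15.8,13.4,2.9,9.6,0.4,1.1,0.0,11.2,1.3,15.3,58.5,1.4
Croatia,Barren,Site1,538.6,81.1,7.2,0.7,57.4,16.6,2.9,0.3,28.7,6.5,24.0,12.2,0.1
Croatia,Barren,Site2,267.2,106.6,4.5,0.8,28.1,3.9,0.6,0.1,13.9,2.0,23.3,15.9,0.2
Croatia,Meadow,Site1,279.4,132.1,10.0,1.0,16.3,1.9,1.4,0.1,12.5,1.2,7.4,39.4,0.6
Croatia,Meadow,Site2,299.2,17.2,8.3,1.5,14.3,3.5,3.1,0.2,12.2,2.3,11.8,33.5,0.6
Montenegro,Barren,Site1,311.4,42.9,6.7,0.1,46.5,3.6,1.4,0.2,22.9,1.2,7.9,14.3,0.1
Montenegro,Barren,Site2,374.4,69.6,1.8,0.3,30.8,4.8,2.8,0.3,15.3,2.2,6.6,5.7,0.1
Montenegro,Meadow,Site1,166.3,105.7,12.1,2.5,10.4,1.9,1.9,0.3,11.5,1.2,13.4,51.5,1.2
Montenegro,Meadow,Site2,90.7,15.8,4.7,0.3,8.8,0.4,3.4,0.0,8.4,0.0,6.0,27.7,0.5
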