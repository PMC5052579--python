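area,state,site,abundance,abundance_sd,biomass,biomass_sd,n_taxa,sr,margalef,pielou,shannon,es22,es51,itd,mi,pct_1a1b,pct_2a,pct_2b
Minorca,Barren,Site1,57.7,32.7,11.7,4.3,10.0,34,5.8,0.8,2.7,10.9,16.8,0.3,2.7,5.1,79.3,15.6
Minorca,Barren,Site2,24.9,11.5,4.5,1.1,9.0,30,6.0,0.8,2.8,12.9,19.8,0.4,3.0,4.0,73.6,22.4
Minorca,Meadow,Site1,182.7,154.8,31.7,9.5,14.0,47,8.3,0.8,3.0,12.3,22.2,0.3,3.0,11.0,82.7,6.3
Minorca,Meadow,Site2,213.7,61.3,43.6,8.7,14.0,49,8.4,0.8,3.0,12.1,20.4,0.3,3.1,9.3,83.0,7.7
Sardinia,Barren,Site1,21.4,14.5,7.2,2.9,12.0,12,2.5,0.8,2.1,8.6,11.0,0.2,2.6,1.2,88.9,9.9
Sardinia,Barren,Site2,12.6,9.7,3.6,1.3,8.0,14,3.7,0.9,2.3,14.6,,0.2,2.6,2.9,88.6,8.6
Sardinia,Meadow,Site1,397.9,171.4,225.8,97.5,17.0,47,8.1,0.9,3.3,10.7,23.7,0.6,3.0,20.0,61.7,18.3
Sardinia,Meadow,Site2,172.2,103.8,44.9,14.2,18.0,57,9.8,0.9,3.4,15.3,25.3,0.6,3.0,21.3,60.3,18.3
Tuscany,Barren,Site1,39.2,19.4,9.3,2.4,15.0,37,7.5,0.9,3.3,15.4,25.3,0.7,3.2,28.6,42.0,29.4
Tuscany,Barren,Site2,38.4,23.8,8.3,2.0,12.0,20,5.2,0.9,2.8,14.6,,0.6,3.1,20.0,52.5,27.5
Tuscany,Meadow,Site1,235.9,122.8,49.9,12.1,17.0,50,8.7,0.9,3.3,13.9,24.6,0.6,3.1,36.9,46.7,16.4
Tuscany,Meadow,Site2,465.4,166.1,96.0,19.5,21.0,64,11.1,0.8,3.5,14.8,26.3,0.6,3.1,30.7,48.4,20.9
Sicily,Barren,Site1,16.0,14.0,2.8,1.6,8.0,11,3.2,0.9,2.2,11.0,,0.6,3.3,18.2,36.4,45.5
Sicily,Barren,Site2,13.3,11.8,2.2,0.7,10.0,12,3.3,1.0,2.4,13.9,,0.5,2.9,3.6,67.9,28.6
Sicily,Meadow,Site1,225.3,77.7,36.0,9.4,16.0,41,7.0,0.9,3.2,11.2,21.7,0.5,3.1,12.3,64.0,23.7
Sicily,Meadow,Site2,204.0,79.1,35.0,7.0,18.0,38,6.5,0.9,3.1,13.7,21.4,0.5,3.1,7.0,64.7,28.3
Croatia,Barren,Site1,32.8,14.5,9.8,2.3,11.0,21,4.1,0.7,2.3,9.3,14.1,0.3,2.8,9.6,81.6,8.8
Croatia,Barren,Site2,51.0,22.1,7.6,0.7,10.0,31,6.0,0.9,3.1,16.2,22.0,0.5,2.7,16.7,66.7,16.7
Croatia,Meadow,Site1,669.7,82.6,130.6,15.8,17.0,68,11.7,0.9,3.7,14.0,28.8,0.7,3.1,35.0,51.2,13.9
Croatia,Meadow,Site2,630.7,242.1,120.3,22.2,18.0,55,9.4,0.8,3.3,14.5,24.3,0.7,3.0,34.1,47.9,18.0
Montenegro,Barren,Site1,31.3,14.3,5.2,1.4,12.0,23,5.3,0.9,2.8,13.4,20.8,0.6,3.2,17.2,54.7,28.1
Montenegro,Barren,Site2,30.9,6.1,6.9,0.8,11.0,33,6.5,0.9,3.0,16.1,21.4,0.6,3.2,15.4,52.9,31.6
Montenegro,Meadow,Site1,290.3,156.1,68.5,17.7,16.0,62,10.7,0.9,3.6,13.3,27.8,0.7,3.3,30.0,45.3,24.7
Montenegro,Meadow,Site2,183.4,35.7,58.6,14.0,15.0,59,10.2,0.9,3.6,16.2,27.7,0.6,2.9,28.0,53.3,18.7
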