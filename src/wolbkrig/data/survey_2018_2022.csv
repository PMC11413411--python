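id,lat,lon,year,n,k,haplotypes,range_label
Austria,48.21,16.37,2021,12,12,HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2,native
Italy,46.5,11.35,2019,12,12,HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2,native
France 1,43.95,4.81,2019,12,12,HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2,native
France 2,43.49,-1.47,2019,12,10,HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1,native
France 3,44.84,-0.58,2019,12,12,HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2,native
France 4,45.76,4.84,2019,12,12,HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2,native
Turkey 1,37.0,35.32,2019,9,0,HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1,native
Turkey 2,39.93,32.86,2019,10,0,HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1,native
Russia,45.04,38.98,2020,12,2,HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2;HT2,native
Greece,40.64,22.94,2019,2,0,HT1;HT1,native
Poland,52.23,21.01,2019,12,10,,native
Sweden,59.33,18.07,2020,12,11,,native
Latvia,56.95,24.11,2020,11,5,,native
Finland,60.17,24.94,2020,5,3,,native
USA,43.17,-78.7,2018,40,0,HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1;HT1,introduced
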