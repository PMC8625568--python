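period,location,source,n_studies,range,estimate_per_100k
1950s,U.K.,Tooth and Brook 1962,1,,180
1960s,Mixed,Bachrach 1975,12,40-219,83.8
1970s,Mixed,Bachrach 1975,9,20-375,89.4
1980s,U.S. mixed states,Goperud 1985,6,24.1-44.0,33.8
2000s,U.S.,Treatment Advocacy Center 2008,1,40-60,50
2010s,U.S. North Carolina,La et al. 2016,1,,39
2015,World / U.S.,Hudson 2020,1,53.5-74.8,64.1
2018,U.S. states,state benchmark model,1,28.1-41.7,34.9
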