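# Demographics, FHS primary care coverage and mortality for the 15 largest
# Brazilian cities (2016). Percentages as printed in the published city table;
# mortality per 1,000 person-years; child mortality per 1,000 live births.
# One adjustment: the published pardo share for Curitiba (58.5) is internally
# inconsistent (White+Black+Pardo = 136.6% vs 96.6-99.6% for all other
# cities); 18.5 is stored instead.
city,pct_under15,pct_over64,pct_female,pct_white,pct_black,pct_pardo,pct_poverty,pct_secondary_edu,fhs_coverage_pct,crude_mortality_per_1000,age_std_mortality_per_1000,infant_mortality_per_1000,under5_mortality_per_1000
Belo Horizonte,29.9,4.7,52.7,40.5,12.6,46.5,5.6,47.5,76.5,5.76,4.95,13.0,15.2
Belém,24.8,5.5,52.1,21.2,9.1,69.3,14.9,37.1,23.5,5.49,6.17,16.1,17.2
Brasília,23.7,5.0,52.2,40.0,10.6,48.3,4.9,53.5,37.8,3.93,4.98,14.0,15.8
Campinas,19.3,5.8,51.8,57.2,8.9,30.8,3.2,53.2,44.5,5.60,4.86,11.8,13.7
Curitiba,20.0,4.9,52.3,74.3,3.8,18.5,1.7,57.8,36.4,5.19,4.86,11.9,13.6
Fortaleza,22.6,4.9,53.2,32.3,5.8,61.4,12.1,45.4,45.9,4.93,5.40,15.8,16.9
Goiânia,20.8,4.2,52.3,43.2,6.4,49.8,3.1,57.0,44.3,5.42,5.99,13.1,15.0
Maceió,25.0,4.4,53.2,27.1,5.6,66.7,15.6,42.6,29.0,5.91,7.04,22.0,24.0
Manaus,28.2,3.2,51.2,20.1,2.3,77.0,12.9,38.8,27.0,4.34,6.84,14.2,15.2
Porto Alegre,18.8,6.4,53.6,78.0,11.4,10.2,3.8,48.2,55.0,7.42,5.43,11.6,13.1
Recife,20.9,5.5,53.8,36.9,9.1,52.7,13.2,46.7,54.8,6.43,6.05,15.6,12.5
Rio de Janeiro,19.4,7.6,53.2,48.5,11.6,39.2,5.0,45.9,62.9,8.14,5.97,13.0,14.6
Salvador,20.7,4.3,53.3,14.8,38.0,46.8,11.4,41.8,26.7,5.32,5.90,14.9,12.0
São Luís,23.7,3.8,53.2,19.9,15.5,63.9,13.8,53.1,34.4,4.64,5.91,18.1,19.8
São Paulo,20.8,5.5,52.6,57.9,8.7,30.4,4.3,50.5,35.4,5.71,5.09,13.2,14.7
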