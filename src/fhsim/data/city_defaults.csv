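# SYNTHETIC DEFAULTS — these columns are NOT part of the published city
# table. Population sizes are round 2016-era census estimates; the Bolsa
# Família participation share is a plausible value (~2x the poverty share);
# crude birth rates (per 1,000 person-years) are plausible for large
# Brazilian cities. They supply pooling weights and live-birth denominators
# and can be overridden by a user-provided file.
city,population,bolsa_familia_pct,crude_birth_rate_per_1000
Belo Horizonte,2513000,12.0,13.5
Belém,1446000,30.0,16.0
Brasília,2977000,10.0,14.5
Campinas,1174000,7.0,13.0
Curitiba,1894000,5.0,13.5
Fortaleza,2609000,25.0,15.0
Goiânia,1448000,7.0,14.0
Maceió,1021000,32.0,16.5
Manaus,2094000,27.0,18.0
Porto Alegre,1482000,8.0,12.0
Recife,1626000,27.0,14.5
Rio de Janeiro,6498000,11.0,12.5
Salvador,2938000,24.0,14.0
São Luís,1082000,28.0,16.0
São Paulo,12038000,9.0,14.0
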