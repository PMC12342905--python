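component,nation,fiscal_year,amount_gbp,price_year,provenance
inpatient,UK,2015/16,5449545832.19,2022,"2015 EHN estimate, UK aggregate"
outpatient,UK,2015/16,899427786.19,2022,"2015 EHN estimate, UK aggregate"
a_and_e,UK,2015/16,333955900.58,2022,"2015 EHN estimate, UK aggregate"
primary_care,UK,2015/16,1372554805.84,2022,"2015 EHN estimate, UK aggregate"
medications,UK,2015/16,2288700449.83,2022,"2015 EHN estimate, UK aggregate"
morbidity,UK,2015/16,2134749896.72,2022,"2015 EHN estimate, UK aggregate"
mortality,UK,2015/16,5196227187.18,2022,"2015 EHN estimate, UK aggregate"
informal_care,UK,2015/16,4663386830.99,2022,"2015 EHN estimate, UK aggregate"
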