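component,nation,fiscal_year,amount_gbp,price_year,provenance
morbidity,England,2019/20,1419679848.96,2022,sickness days x daily wage + ESA/DLA claims
morbidity,Scotland,2019/20,192876488.60,2022,sickness days x daily wage + ESA/DLA claims
morbidity,Wales,2019/20,114661775.69,2022,sickness days x daily wage + ESA/DLA claims
morbidity,NorthernIreland,2019/20,77757841.65,2022,sickness days x daily wage + ESA/DLA claims
morbidity,England,2020/21,1059000522.69,2022,sickness days x daily wage + ESA/DLA claims
morbidity,Scotland,2020/21,149031457.97,2022,sickness days x daily wage + ESA/DLA claims
morbidity,Wales,2020/21,98244014.10,2022,sickness days x daily wage + ESA/DLA claims
morbidity,NorthernIreland,2020/21,64853213.10,2022,sickness days x daily wage + ESA/DLA claims
morbidity,England,2021/22,1175542772.43,2022,sickness days x daily wage + ESA/DLA claims
morbidity,Scotland,2021/22,136032383.51,2022,sickness days x daily wage + ESA/DLA claims
morbidity,Wales,2021/22,101492987.92,2022,sickness days x daily wage + ESA/DLA claims
morbidity,NorthernIreland,2021/22,67540337.90,2022,sickness days x daily wage + ESA/DLA claims
mortality,England,2019/20,3363716186.66,2022,modelled: human-capital present value of earnings to 65
mortality,Scotland,2019/20,456442067.99,2022,modelled: human-capital present value of earnings to 65
mortality,Wales,2019/20,234007757.42,2022,modelled: human-capital present value of earnings to 65
mortality,NorthernIreland,2019/20,115973175.44,2022,modelled: human-capital present value of earnings to 65
mortality,England,2020/21,3622785839.23,2022,modelled: human-capital present value of earnings to 65
mortality,Scotland,2020/21,485383301.09,2022,modelled: human-capital present value of earnings to 65
mortality,Wales,2020/21,247939694.93,2022,modelled: human-capital present value of earnings to 65
mortality,NorthernIreland,2020/21,116145077.46,2022,modelled: human-capital present value of earnings to 65
mortality,England,2021/22,3669492556.71,2022,modelled: human-capital present value of earnings to 65
mortality,Scotland,2021/22,504266240.34,2022,modelled: human-capital present value of earnings to 65
mortality,Wales,2021/22,257445031.12,2022,modelled: human-capital present value of earnings to 65
mortality,NorthernIreland,2021/22,112772446.81,2022,modelled: human-capital present value of earnings to 65
informal_care,England,2019/20,4772804883.59,2022,modelled: survey marginal effects x hours x wage
informal_care,Scotland,2019/20,495126560.14,2022,modelled: survey marginal effects x hours x wage
informal_care,Wales,2019/20,293301540.45,2022,modelled: survey marginal effects x hours x wage
informal_care,NorthernIreland,2019/20,153584534.77,2022,modelled: survey marginal effects x hours x wage
informal_care,England,2020/21,4539578016.63,2022,modelled: survey marginal effects x hours x wage
informal_care,Scotland,2020/21,469157142.94,2022,modelled: survey marginal effects x hours x wage
informal_care,Wales,2020/21,278197853.56,2022,modelled: survey marginal effects x hours x wage
informal_care,NorthernIreland,2020/21,146443088.54,2022,modelled: survey marginal effects x hours x wage
informal_care,England,2021/22,5326626027.01,2022,modelled: survey marginal effects x hours x wage
informal_care,Scotland,2021/22,552098576.72,2022,modelled: survey marginal effects x hours x wage
informal_care,Wales,2021/22,323745534.30,2022,modelled: survey marginal effects x hours x wage
informal_care,NorthernIreland,2021/22,174459080.12,2022,modelled: survey marginal effects x hours x wage
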