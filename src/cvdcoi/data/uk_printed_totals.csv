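quantity,fiscal_year,amount_gbp
inpatient,2019/20,5902562012.59
inpatient,2020/21,6258547282.76
inpatient,2021/22,6732456821.82
outpatient,2019/20,900995134.97
outpatient,2020/21,924269717.97
outpatient,2021/22,1010695676.09
a_and_e,2019/20,357042291.74
a_and_e,2020/21,392362590.87
a_and_e,2021/22,327626962.37
primary_care,2019/20,1423677763.98
primary_care,2020/21,1265861038.04
primary_care,2021/22,1555641199.16
medications,2019/20,1805967156.62
medications,2020/21,1853979414.91
medications,2021/22,1940427596.98
devices,2019/20,307116365.46
devices,2020/21,243893010.21
devices,2021/22,404371349.20
ltc,2019/20,3903440803.45
ltc,2020/21,4384334226.00
ltc,2021/22,4648757713.68
total_direct_without_ltc_devices,2015/16,10344184774.63
total_direct_without_ltc_devices,2019/20,10390244359.89
total_direct_without_ltc_devices,2020/21,10695020044.55
total_direct_without_ltc_devices,2021/22,11566848256.42
total_direct_with_ltc_devices,2019/20,14600801528.80
total_direct_with_ltc_devices,2020/21,15323247280.76
total_direct_with_ltc_devices,2021/22,16619977319.30
morbidity,2019/20,1804975954.90
morbidity,2020/21,1371129207.87
morbidity,2021/22,1480608481.76
mortality,2019/20,4170139187.51
mortality,2020/21,4472253912.71
mortality,2021/22,4543976274.97
informal_care,2019/20,5714817518.95
informal_care,2020/21,5433376101.67
informal_care,2021/22,6376929218.16
total_indirect,2015/16,11994363914.90
total_indirect,2019/20,11689932661.36
total_indirect,2020/21,11276759222.25
total_indirect,2021/22,12401513974.89
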