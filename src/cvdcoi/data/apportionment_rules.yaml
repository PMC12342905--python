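# Versioned registry of top-down apportionment shares.
# Each rule: share in [0,1] and the source it was taken from.
general_medicine_cvd:
  share: 0.179
  source: "pan-European survey of General Medicine case-mix: 17.9% of admissions CVD-related"
stroke_tia_to_neurology:
  share: 0.30
  source: "NHS England ratio of Stroke and TIA services to Neurology services"
vascular_to_general_surgery:
  share: 0.072
  source: "NHS England ratio of vascular surgery to general surgery outpatient activity"
primary_care_cvd:
  share: 0.12
  source: "proportion of GP consultations attributable to hypertension (2017), used as CVD proxy"
vad_share_of_dementia:
  share: 0.17
  source: "proportion of all dementia attributed to vascular dementia"
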