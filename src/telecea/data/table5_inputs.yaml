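# Trial-derived per-consultation unit costs and outcomes.
# travel_per_consultation includes the patient-paid user fee;
# production_loss_per_consultation is the travel+time total minus travel
# (182.50 - 148.65 and 51.77 - 40.73 respectively).
currency: EUR
user_fee: 31.04
volume_assumed: 300
arms:
  standard:
    travel_per_consultation: 148.65
    production_loss_per_consultation: 33.85
    qaly_gain: 0.05
  telemedicine:
    travel_per_consultation: 40.73
    production_loss_per_consultation: 11.04
    qaly_gain: 0.09
qaly_p_value: 0.29
distances:
  standard_mean_km: 248.0     # mean reported one-way distance, hospital arm
  telemedicine_mean_km: 47.0  # mean reported one-way distance, remote-clinic arm
  clinic_hospital_km: 148.0   # road distance between remote clinic and hospital
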