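# Calibrated fare schedule (euros). The official reimbursement tables are not
# redistributable, so these unit fares are calibrated such that pricing the
# default synthetic cohort reproduces the observed arm-mean travel cost per
# consultation (148.65 standard / 40.73 telemedicine, user fee included) and
# travel+time totals (182.50 / 51.77).
# Pricing model per consultation:
#   total = user_fee
#         + [per_trip(main mode) + per_km(main mode) * 2 * one_way_km]
#           * (1 + companion_multiplier if companion)
#         + extra_transport_surcharge (if extra transport needed)
# The user fee is the patient-paid share; the remainder is health-sector.
currency: EUR
per_km:
  private_car: 0.0695
  taxi: 0.085
  bus: 0.32
  express_boat: 0.49
  ferry: 0.20
  airplane: 0.0
  other: 0.0
per_trip:
  private_car: 0.0
  taxi: 2.0
  bus: 0.0
  express_boat: 50.0
  ferry: 15.0
  airplane: 350.0
  other: 0.0
companion_multiplier: 0.4
extra_transport_surcharge: 5.0
user_fee: 31.04
average_hourly_wage: 25.0
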