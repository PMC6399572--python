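# Service cost configuration for the video-assisted outpatient clinic.
# Amounts are euros (converted once, at 9.60 NOK/EUR, when sourced in NOK).
# category: investment (present value, annuitized), recurring_annual (EUR/year),
#           per_consultation (EUR per single consultation).
# alternative: telemedicine_A (standard videoconferencing units),
#              telemedicine_B (desktop/Skype solution),
#              shared (common to both telemedicine alternatives),
#              standard (in-person hospital consultation arm).
currency: EUR
annuity:
  discount_rate: 0.03
  lifetime_years: 5
reference_volume: 300
components:
  # --- Alternative A investments -------------------------------------------
  - name: videoconferencing unit, hospital
    amount: 5104
    category: investment
    site: hospital
    alternative: telemedicine_A
    payer: health_sector
  - name: videoconferencing unit, remote center
    amount: 6250
    category: investment
    site: remote_center
    alternative: telemedicine_A
    payer: health_sector
  - name: screen, remote center
    amount: 156
    category: investment
    site: remote_center
    alternative: telemedicine_A
    payer: health_sector
  # --- Alternative B investments -------------------------------------------
  - name: web camera, hospital
    amount: 96
    category: investment
    site: hospital
    alternative: telemedicine_B
    payer: health_sector
  - name: camera/microphone group unit, remote center
    amount: 937
    category: investment
    site: remote_center
    alternative: telemedicine_B
    payer: health_sector
  - name: two signage screens, remote center
    amount: 1666
    category: investment
    site: remote_center
    alternative: telemedicine_B
    payer: health_sector
  - name: table microphone, hospital
    amount: 111
    category: investment
    site: hospital
    alternative: telemedicine_B
    payer: health_sector
  # --- Investments common to both telemedicine alternatives ----------------
  - name: personal computer, remote center
    amount: 463
    category: investment
    site: remote_center
    alternative: shared
    payer: health_sector
  - name: printer, remote center
    amount: 114
    category: investment
    site: remote_center
    alternative: shared
    payer: health_sector
  - name: initial training of nurse and physician
    amount: 4424
    category: investment
    site: shared
    alternative: shared
    payer: health_sector
  # --- Recurring annual costs ----------------------------------------------
  - name: line rental, secure health network
    amount: 1250  # 104/month
    category: recurring_annual
    site: remote_center
    alternative: telemedicine_A
    payer: health_sector
  - name: rent for extra space, remote center
    amount: 3542
    category: recurring_annual
    site: remote_center
    alternative: shared
    payer: health_sector
  - name: nurse in 20% position, remote center
    amount: 12083
    category: recurring_annual
    site: remote_center
    alternative: shared
    payer: health_sector
  # --- Volume-driven costs --------------------------------------------------
  - name: second consultation at the hospital (5 per 300 consultations)
    amount: 0.68  # 204 EUR/year at the 300-consultation reference volume
    category: per_consultation
    site: hospital
    alternative: shared
    payer: health_sector
  # --- Standard consultation arm -------------------------------------------
  - name: nurse assistance during standard consultations (32% of consultations)
    amount: 906  # ~25 hours/year at the 300-consultation reference volume
    category: recurring_annual
    site: hospital
    alternative: standard
    payer: health_sector
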