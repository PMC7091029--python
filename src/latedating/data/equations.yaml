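# Dating-equation registry, version 1.
#
# Coefficients are configuration data, not code. Individual-parameter records
# carry published nomogram coefficients where the source prints them; the two
# multi-parameter records are calibrated log-linear stand-ins fitted to the
# self-consistent growth curves implied by the individual records (swap in
# transcribed published coefficients by editing this file).
equations:
  - name: intergrowth_crl
    required_parameters: [CRL]
    functional_form: crl_sqrt
    coefficients: [40.9041, 3.21585, 0.348956]
    valid_range:
      CRL: [2.0, 95.0]
    input_unit: mm
    output_unit: days
    source: "INTERGROWTH-21st first-trimester crown-rump-length dating equation (Papageorghiou et al. 2014)"
  - name: hadlock_bpd
    required_parameters: [BPD]
    functional_form: polynomial
    coefficients: [9.54, 1.482, 0.1676]
    valid_range:
      BPD: [3.0, 11.0]
    input_unit: cm
    output_unit: weeks
    source: "Hadlock et al. 1984 GA-from-BPD regression"
  - name: hadlock_fl
    required_parameters: [FL]
    functional_form: polynomial
    coefficients: [10.35, 2.46, 0.17]
    valid_range:
      FL: [2.0, 9.0]
    input_unit: cm
    output_unit: weeks
    source: "Hadlock et al. 1984 GA-from-FL regression"
  - name: hadlock_ac
    required_parameters: [AC]
    functional_form: polynomial
    coefficients: [8.14, 0.753, 0.0036]
    valid_range:
      AC: [12.0, 42.0]
    input_unit: cm
    output_unit: weeks
    source: "Hadlock et al. 1984 GA-from-AC regression"
  - name: intergrowth_hc
    required_parameters: [HC]
    functional_form: hc_log
    coefficients: [3.3258, 0.0597, 6.409e-09]
    valid_range:
      HC: [10.0, 38.0]
    input_unit: mm
    output_unit: days
    source: "INTERGROWTH-21st late-pregnancy GA-from-HC equation (Papageorghiou et al. 2016); valid range capped at 38 cm to keep GA below 330 d"
  - name: chavez_tcd
    required_parameters: [TCD]
    functional_form: log_linear
    coefficients: [37.0, 143.0]
    valid_range:
      TCD: [1.5, 6.0]
    input_unit: cm
    output_unit: days
    source: "Log-linear stand-in for the Chavez et al. 2004 GA-from-TCD nomogram (calibrated to published centile tables; replace with transcribed coefficients if available)"
  - name: hadlock_combo
    required_parameters: [BPD, FL, AC]
    functional_form: log_linear
    coefficients: [-207.4127, 68.5565, 57.8043, 56.0884]
    valid_range:
      BPD: [3.0, 11.0]
      FL: [2.5, 9.0]
      AC: [12.0, 42.0]
    input_unit: cm
    output_unit: days
    source: "Log-linear stand-in for the Hadlock et al. 1984 BPD+FL+AC combination formula, calibrated to the individual-record growth curves over 160-268 d"
  - name: intergrowth_combo
    required_parameters: [HC, FL]
    functional_form: log_linear
    coefficients: [-303.5527, 110.5241, 86.7064]
    valid_range:
      HC: [12.0, 38.0]
      FL: [2.8, 9.0]
    input_unit: cm
    output_unit: days
    source: "Log-linear stand-in for the INTERGROWTH-21st HC+FL late-pregnancy combination formula, calibrated to the individual-record growth curves over 160-268 d"
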