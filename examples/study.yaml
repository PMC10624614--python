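# Full default study configuration: 5/7/7 cohort, 60-min epoch at 1 h after
# insult onset, seven signal pairs, both index kinds.
seed: 1

cohort:
  n_per_group: {control: 5, moderate: 7, severe: 7}
  duration_s: 9000          # 2.5 h of recording per subject
  insult_onset_s: 900       # after a 15-min baseline
  noise_sd_frac: 0.05
  drift_amp_frac: 0.5
  artifact_rate_per_hour: 0 # set >0 to exercise the artifact machinery

analysis:
  band_hz: [0.003, 0.05]
  target_rate_hz: 1.0
  artifact_threshold_frac: 0.15
  epoch: {start_s: 3600, duration_s: 3600}
  pair_list:
    - [BFI, HbD]
    - [oxCCO, HbD]
    - [oxCCO, HbT]
    - [BFI, MABP]
    - [BFI, HbT]
    - [BFI, oxCCO]
    - [oxCCO, MABP]
  lacnaa_threshold: 0.39
  alpha: 0.05
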