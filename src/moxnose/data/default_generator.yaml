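# Default synthetic-generator parameters for the eight-channel array.
#
# Class effects are multiplicative on the response amplitude A (fraction of
# the baseline resistance) and on the response time constant tau_resp:
#   - the 24-month seasoning responds deeper and faster than the 12-month one
#     (seasoning_tau for M12 is tuned so the two seasonings' 10-90 % fall
#     times differ by about 5 s at the default tau_resp_s of 7 s);
#   - the rind class scales amplitude (more rind, stronger aroma signature);
#   - the working process leaves kinetics alone but re-weights amplitudes
#     across channels (process_amp below, per sensor), i.e. WR and SR differ
#     by their response *pattern*, not by overall intensity.
noise_sd: 0.005        # relative Gaussian measurement noise on R
replica_cv: 0.08       # lognormal between-replica CV on the amplitude
effects:
  seasoning_amp: {M12: 0.75, M24: 1.0}
  seasoning_tau: {M12: 1.3254, M24: 1.0}
  rind_amp: {LE18: 0.78, PCT19_26: 1.0, GT26: 1.28}
sensors:
  RGTO_SnO2Au_400:
    amplitude: 0.42
    tau_resp_s: 7.0
    tau_rec_s: 24.0
    baseline_ohm: 8.0e+5
    process_amp: {WR: 1.0, SR: 1.25, NONE: 1.0}
  RGTO_SnO2_300:
    amplitude: 0.20
    tau_resp_s: 7.0
    tau_rec_s: 30.0
    baseline_ohm: 2.5e+5
    process_amp: {WR: 1.0, SR: 0.80, NONE: 1.0}
  RGTO_SnO2_400:
    amplitude: 0.40
    tau_resp_s: 7.0
    tau_rec_s: 26.0
    baseline_ohm: 4.0e+5
    process_amp: {WR: 1.0, SR: 1.0, NONE: 1.0}
  NW_SnO2Au_350:
    amplitude: 0.45
    tau_resp_s: 7.0
    tau_rec_s: 22.0
    baseline_ohm: 6.0e+5
    process_amp: {WR: 1.0, SR: 1.25, NONE: 1.0}
  NW_SnO2_350:
    amplitude: 0.38
    tau_resp_s: 7.0
    tau_rec_s: 25.0
    baseline_ohm: 5.0e+5
    process_amp: {WR: 1.0, SR: 0.80, NONE: 1.0}
  NW_CuO_400:
    amplitude: 0.30
    tau_resp_s: 7.0
    tau_rec_s: 28.0
    baseline_ohm: 9.0e+4
    process_amp: {WR: 1.0, SR: 0.80, NONE: 1.0}
  TGS2611:
    amplitude: 0.25
    tau_resp_s: 7.0
    tau_rec_s: 20.0
    baseline_ohm: 3.0e+4
    process_amp: {WR: 1.0, SR: 1.25, NONE: 1.0}
  TGS2602:
    amplitude: 0.35
    tau_resp_s: 7.0
    tau_rec_s: 23.0
    baseline_ohm: 4.5e+4
    process_amp: {WR: 1.0, SR: 0.80, NONE: 1.0}
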