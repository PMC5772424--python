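# Default demographic models and priors for the Bornean elephant analysis.
#
# Sizes are effective diploid individuals; times are generations before
# present; `loguniform` bounds are base-10 exponents.  The AC/RI/ACS/RIS
# blocks follow the published prior table of the original microsatellite ABC
# study; the ID/ED/TI priors (not published) are package defaults chosen to
# span both historical introduction events (late-13th-century Java->Sulu,
# ~1673 Sulu->Sabah, i.e. ~20-45 generations at 15 y/generation) as well as
# the ancient-colonization window.  The mean microsatellite mutation rate mu
# (per locus per generation) and the multistep-mutation parameter p_gsm are
# shared across models.  The fragmentation time T_split of the structured
# models (ACS/RIS) defaults to a recent window (1-20 generations, ~15-300
# years): Sabah's fragmentation is anthropogenic and recent, and a recent
# split is the reading under which the simple and structured versions of a
# model are nearly indistinguishable, as reported for the original analysis.
generation_time_years: 15

models:
  ID:
    demes: 1
    priors:
      N_anc: {kind: loguniform, min: 4, max: 5}
      N_cur: {kind: loguniform, min: 2.4, max: 3}
      T_shrink: {kind: uniform, min: 20, max: 1500}
      mu: {kind: loguniform, min: -5, max: -3}
      p_gsm: {kind: uniform, min: 0.0, max: 0.3}
  ED:
    demes: 1
    priors:
      N_anc: {kind: loguniform, min: 4, max: 5}
      N_cur: {kind: loguniform, min: 2.4, max: 3}
      T_shrink: {kind: uniform, min: 20, max: 1500}
      mu: {kind: loguniform, min: -5, max: -3}
      p_gsm: {kind: uniform, min: 0.0, max: 0.3}
  AC:
    demes: 1
    priors:
      N_anc: {kind: loguniform, min: 4, max: 5}
      N_cur: {kind: loguniform, min: 2.4, max: 3}
      T_shrink: {kind: uniform, min: 1000, max: 1500}
      N_shrink: {kind: uniform, min: 4, max: 50}
      mu: {kind: loguniform, min: -5, max: -3}
      p_gsm: {kind: uniform, min: 0.0, max: 0.3}
  RI:
    demes: 1
    priors:
      N_anc: {kind: loguniform, min: 2.4, max: 4}
      N_cur: {kind: loguniform, min: 2.4, max: 3}
      T_shrink: {kind: uniform, min: 20, max: 70}
      N_shrink: {kind: uniform, min: 2, max: 50}
      mu: {kind: loguniform, min: -5, max: -3}
      p_gsm: {kind: uniform, min: 0.0, max: 0.3}
  TI:
    demes: 1
    priors:
      N_anc: {kind: loguniform, min: 2.4, max: 4}
      N_intermediate: {kind: loguniform, min: 2.4, max: 4}
      N_cur: {kind: loguniform, min: 2.4, max: 3}
      T_shrink: {kind: uniform, min: 20, max: 70}
      T_first: {kind: uniform, min: 40, max: 70}
      N_shrink: {kind: uniform, min: 2, max: 50}
      N_shrink_first: {kind: uniform, min: 2, max: 50}
      mu: {kind: loguniform, min: -5, max: -3}
      p_gsm: {kind: uniform, min: 0.0, max: 0.3}
  ACS:
    demes: 4
    priors:
      N_anc: {kind: loguniform, min: 4, max: 5}
      N_cur: {kind: loguniform, min: 2.4, max: 3}
      T_shrink: {kind: uniform, min: 1000, max: 1500}
      N_shrink: {kind: uniform, min: 8, max: 50}
      T_split: {kind: uniform, min: 1, max: 20}
      mu: {kind: loguniform, min: -5, max: -3}
      p_gsm: {kind: uniform, min: 0.0, max: 0.3}
  RIS:
    demes: 4
    priors:
      N_anc: {kind: loguniform, min: 2.4, max: 4}
      N_cur: {kind: loguniform, min: 2.4, max: 3}
      T_shrink: {kind: uniform, min: 20, max: 70}
      N_shrink: {kind: uniform, min: 8, max: 50}
      T_split: {kind: uniform, min: 1, max: 20}
      mu: {kind: loguniform, min: -5, max: -3}
      p_gsm: {kind: uniform, min: 0.0, max: 0.3}
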