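# Default two-cohort phantom study: anterior (ACA-like) vs posterior-shifted
# ventral (IL/PL-like) medial prefrontal injections, 10 subjects per group,
# four sessions each, 0.1 mm isotropic.  All stages derive their randomness
# from the master seed.
mode: phantom
phantom:
  n_subjects_per_group: 10
q_within: 0.05
q_between: 0.01
fwhm_mm: 0.3
dynamics_delta: 0.05
roi_segments: [DS, RTN, SNr, BLA]
output_dir: results/study
seed: 1
write_intermediates: false
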