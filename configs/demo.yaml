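# Demo end-to-end run: small synthetic allohexaploid panel with planted
# homoeologous sweeps on 1A/1B and a D-genome introgression tract.
seed: 7
simulate:
  subgenomes:
    A:
      chromosomes: [{name: "1A", length_bp: 120000000, map_cm: 60.0, n_snps: 1200}]
      founders: 16
      spectrum_skew: 1.0
    B:
      chromosomes: [{name: "1B", length_bp: 120000000, map_cm: 60.0, n_snps: 1200}]
      founders: 16
      spectrum_skew: 1.0
    D:
      chromosomes: [{name: "1D", length_bp: 120000000, map_cm: 60.0, n_snps: 480}]
      founders: 8
      spectrum_skew: 1.5
  sweeps:
    - {chrom: "1A", center_bp: 60000000, half_width_bp: 5000000, carrier_fraction: 0.4}
    - {chrom: "1B", center_bp: 60000000, half_width_bp: 5000000, carrier_fraction: 0.4}
  introgressions:
    - tracts: [["1D", 20000000, 40000000]]
      divergence: 0.9
      recipient_fraction: 0.5
filter:
  min_called_lines: 46
  max_het_lines: 1
  min_maf: 0.016
diversity:
  win_bp: 2000000
  step_bp: 1000000
  tail_fraction: 0.025
  tails: both
phs:
  window_bp: 50000
  merge_gap_bp: 1000000
  bin_width: 0.05
  tail_fraction: 0.025
  min_bin_count: 200
overlap:
  n_perm: 500
  seed: 8
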