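# Default end-to-end run: a synthetic 36-sheep panel with ~110 cells per
# smear, the published subpopulation mixture, and the published grouping
# cut-offs.  All units: calibration um/px, areas um^2, lengths um.
seed: 0
output_dir: erymorph_out
calibration: 0.05
n_sheep: 36
cells_per_sheep: 110
demo_image: true
demo_image_cells: 20
threshold: null        # null = Otsu on the luminance
min_area_um2: 6.0      # debris floor
max_area_um2: 32.0     # fused-component ceiling
min_solidity: 0.95     # fused-component solidity rule
smooth_sigma: 2.0      # contour smoothing, in boundary vertices
k_range: [2, 3, 4, 5, 6]
strict_multiplier: 3.0 # robust-clustering hold-out multiplier
min_proportion: 0.05   # clusters below this share are merged
groupings: null        # null = published cut-offs (HGB<=90 ... RDW<=22)
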