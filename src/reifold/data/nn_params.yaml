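# Nearest-neighbor free-energy parameter file (37 C, kcal/mol).
#
# Turner-style model: base-pair stacking free energies (including G-U wobble),
# tabulated loop initiation penalties for hairpin, bulge and internal loops,
# a Ninio-style internal-loop asymmetry term, an affine multiloop score, and a
# 0.5 kcal/mol penalty for each helix end closed by a non-GC (A-U or G-U) pair.
# Loop initiations beyond the tabulated size range are extrapolated
# logarithmically: E(n) = E(max_tabulated) + lxc * ln(n / max_tabulated),
# the Jacobson-Stockmayer form with lxc = 1.75 * R * T.
#
# The model deliberately excludes dangling ends, coaxial stacking, tetraloop
# bonuses and the tabulated 1x1/2x2 internal-loop terms; the folding engine is
# driven entirely by this file, so a richer parameter set can be swapped in.
#
# Stack values are indexed [closing pair][inner pair] for the motif
#   5'-X A-3'
#   3'-Y B-5'
# with closing pair XY and inner pair AB.

min_hairpin: 3          # minimum unpaired nt in a hairpin loop
max_loop: 30            # maximum total unpaired nt in a bulge/internal loop
terminal_nonGC_penalty: 0.5
lxc: 1.08               # log-extrapolation coefficient, kcal/mol

ninio:
  per_nt: 0.6           # internal-loop asymmetry penalty per unpaired-nt difference
  max: 3.0

multiloop:
  closing: 9.3          # affine multiloop: closing + per-branch + per-unpaired
  branch: -0.9
  unpaired: 0.0

pair_order: [CG, GC, GU, UG, AU, UA]

stack:
  CG: [-2.4, -3.3, -2.1, -1.4, -2.1, -2.1]
  GC: [-3.3, -3.4, -2.5, -1.5, -2.2, -2.4]
  GU: [-2.1, -2.5,  1.3, -0.5, -1.4, -1.3]
  UG: [-1.4, -1.5, -0.5,  0.3, -0.6, -1.0]
  AU: [-2.1, -2.2, -1.4, -0.6, -1.1, -0.9]
  UA: [-2.1, -2.4, -1.3, -1.0, -0.9, -1.3]

# hairpin loop initiation, sizes 3..30
hairpin:
  [5.4, 5.6, 5.7, 5.4, 6.0, 5.5, 6.4, 6.5, 6.6, 6.7, 6.78, 6.86, 6.94,
   7.01, 7.07, 7.13, 7.19, 7.25, 7.30, 7.35, 7.40, 7.44, 7.49, 7.53,
   7.57, 7.61, 7.65, 7.69]

# bulge loop initiation, sizes 1..30 (a 1-nt bulge keeps the flanking stack)
bulge:
  [3.8, 2.8, 3.2, 3.6, 4.0, 4.4, 4.59, 4.70, 4.80, 4.90, 5.00, 5.10,
   5.19, 5.27, 5.34, 5.41, 5.48, 5.54, 5.60, 5.65, 5.71, 5.76, 5.80,
   5.85, 5.89, 5.94, 5.98, 6.02, 6.05, 6.09]

# internal loop initiation, total unpaired sizes 2..30
internal:
  [1.5, 1.6, 1.1, 2.0, 2.0, 2.1, 2.3, 2.4, 2.5, 2.6, 2.7, 2.78, 2.86,
   2.94, 3.01, 3.07, 3.13, 3.19, 3.25, 3.30, 3.35, 3.40, 3.45, 3.49,
   3.53, 3.57, 3.61, 3.65, 3.69]
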