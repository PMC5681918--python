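# atriakur baseline parameter file, version 1.
#
# Baseline maximal conductances / transport rates of the human atrial
# cardiomyocyte model (Grandi-Pandit-Voigt human atrial formulation) and the
# chronic-AF (cAF) ionic-remodeling multipliers adopted by this package.
#
# Adopted cAF remodeling set (applied multiplicatively to the nSR baseline,
# before any user scale factors):
#   g_na        x 0.90   (-10% INa)
#   g_to        x 0.30   (-70% transient-outward K+)
#   p_ca        x 0.50   (-50% L-type Ca2+ permeabilities, Ca/K/Na jointly)
#   g_kur       x 0.50   (-50% ultra-rapid delayed-rectifier K+; Kv1.5)
#   g_k1        x 2.00   (+100% inward rectifier)
#   g_ks        x 2.00   (+100% slow delayed rectifier)
#   ibar_ncx    x 1.40   (+40% Na+/Ca2+ exchange)
#   ryr_ko_ca   10 -> 30 uM^-2 ms^-1 (RyR Ca-sensitization; handled as x3)
#   sr_leak     x 1.25   (+25% SR Ca2+ leak)
# All other parameters are phenotype-independent.
#
# Units: conductances mS/uF; ICaL permeability cm/s; INaK/INCX/ICaP maximal
# currents A/F; SERCA Vmax mM/ms; RyR release rate ms^-1; SR leak rate ms^-1.

version: 1

stimulus:
  amplitude: 12.5        # A/F, ~2x diastolic threshold; 5-ms pulse
  duration: 5.0          # ms

baseline:                # nSR values; the 18 scalable parameters
  g_na:        23.0      # fast Na+ conductance
  g_nab:       0.597e-3  # background Na+
  g_to:        0.165     # transient-outward K+ (fast component only, atrial)
  g_kr:        0.035     # rapid delayed rectifier (x sqrt(Ko/5.4))
  g_ks:        0.0035    # slow delayed rectifier
  g_k1:        0.0525    # inward rectifier (x sqrt(Ko/5.4))
  g_kp:        0.002     # plateau K+
  g_kur:       0.045     # ultra-rapid delayed rectifier, Kv1.5 (Markov)
  g_clca:      0.0548    # Ca2+-activated Cl-
  g_clb:       9.0e-3    # background Cl-
  p_ca:        2.7e-4    # L-type Ca2+ permeability (pK, pNa scaled with it)
  g_cab:       6.0643e-4 # background Ca2+
  ibar_nak:    1.26      # Na+/K+ pump
  ibar_ncx:    3.15      # Na+/Ca2+ exchanger
  ibar_pmca:   0.0471    # sarcolemmal Ca2+ pump
  vmax_serca:  5.3114e-3 # SR Ca2+ uptake
  ks_ryr:      25.0      # RyR release rate
  k_sr_leak:   5.348e-6  # passive SR leak rate

caf_multipliers:
  g_na:        0.90
  g_to:        0.30
  p_ca:        0.50
  g_kur:       0.50
  g_k1:        2.0
  g_ks:        2.0
  ibar_ncx:    1.40
  ryr_ko_ca:   3.0
  k_sr_leak:   1.25
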