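"""Steady-state action potential and Ca2+ transient in nSR vs cAF.

Equilibrates the atrial cardiomyocyte model for the fixed beat count at
1 Hz and prints the final-beat biomarkers for both phenotypes.
"""

from atriakur import biomarkers, build_parameters, run_paced

for phenotype in ("nSR", "cAF"):
    params = build_parameters(phenotype)
    trace = run_paced(params, rate_hz=1.0, n_beats=300)
    b = biomarkers(trace)
    print(f"{phenotype} @ 1 Hz: APD40={b.apd40:6.1f} ms  "
          f"APD90={b.apd90:6.1f} ms  CaT_amp={b.cat_amp:6.1f} nM  "
          f"diastolic={b.diastolic_ca:6.1f} nM  dV/dt_max={b.dvdt_max:5.0f} V/s")

# cAF remodeling (halved G_Kur among other changes) shortens the AP and
# depresses the Ca2+ transient relative to normal sinus rhythm -- the
# substrate the Kv1.5-blocker screening works against.
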