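"""Most-probable-number estimation from a dilution-series bioassay.

Each assay pot at dilution d with soil volume v is colonized with
probability 1 - exp(-lambda*d*v); the propagule density lambda is
estimated by maximum likelihood with a profile-likelihood 95% CI.
"""

from amfniche import mpn
from amfniche.synth import SynthConfig, make_dilution_series

# a single series, estimated with its confidence interval
series = mpn.DilutionSeries.from_rows([
    # (dilution, volume mL, n tested, n positive)
    (2 ** -1, 20.0, 10, 4),
    (2 ** -3, 20.0, 10, 1),
    (2 ** -5, 20.0, 10, 0),
    (2 ** -7, 20.0, 10, 0),
])
est = mpn.mpn_estimate(series)
print(f"point estimate {est.density:.4f} propagules/mL soil "
      f"(95% CI {est.ci_low:.4f}-{est.ci_high:.4f})")

# per-trial means over replicated block-level assays, from the generator
cfg = SynthConfig(seed=0)
out = mpn.mpn_batch(make_dilution_series(cfg))
print("\nper-trial bioassay summary (mean +/- SE over blocks):")
print(out.round(4))
print(f"\ntrue densities: {dict(zip(['T1','T2','T3'], cfg.propagule_density))}"
      "\nT3's order-of-magnitude denser propagule bank is resolved even with"
      "\nfour plants per dilution level.")
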