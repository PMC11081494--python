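"""Two-genotype cohort replay: wild-type-like vs twist-like synthetic embryos.

Simulates three embryos per genotype (wild-type-like embryos experience a DV
pull during the mesoderm-invagination window, -13 to +7 min; twist-like
embryos do not), synchronises the movies to extension onset from their AP
tissue strain rate, and tests every 30-s bin for a genotype difference with
a mixed-effects model (random intercept per embryo, alpha 0.01).

Takes a couple of minutes at the full study scale.
"""

import warnings

warnings.filterwarnings("ignore")

from epimorph.pipeline import PipelineConfig, run_pipeline  # noqa: E402
from epimorph.synth import DV_PULL_WINDOW  # noqa: E402

results = run_pipeline(PipelineConfig(seed=1))

print("synchronisation offsets (min):")
for movie, off in results["offsets"].items():
    print(f"  {movie}: {off:+.2f}")
print()
for metric, label in [("shape_dv", "DV cell-shape strain rate"),
                      ("shape_ap", "AP cell-shape strain rate")]:
    cmp_df = results["comparisons"][metric]
    sig = cmp_df[cmp_df.significant]
    window = (f"{sig.bin.min():+.1f} to {sig.bin.max():+.1f} min"
              if len(sig) else "none")
    print(f"{label}: {len(sig)} significant bins ({window})")
print()
print(f"The scripted DV pull runs {DV_PULL_WINDOW[0]:+.0f} to "
      f"{DV_PULL_WINDOW[1]:+.0f} min in wild-type-like embryos only, so the")
print("DV cell-shape comparison lights up inside that window while the AP")
print("metric — identical between genotypes by construction — stays quiet.")
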