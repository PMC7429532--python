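"""Run the full synthetic benchmark on a small cohort.

Simulates patients with known irritative zones, localizes every spike with
the Bayesian map, MUSIC and wMNE against a fitted-ECD benchmark, and runs
the whole evaluation chain: discrepancy metrics, lobar percentages,
concordance with the (synthetic) surgical plan, and outcome prediction.
"""

import warnings

from izbench import CohortConfig, RunConfig, run_pipeline

warnings.simplefilter("ignore")

config = RunConfig(
    seed=3,
    methods=("sesame", "rap_music", "wmne"),
    benchmark="ecd",
    cohort=CohortConfig(
        n_patients=8,
        ied_count_range=(5, 12),
        snr=5.0,  # typical single-spike power SNR
        jitter_mm=10.0,
    ),
)
result = run_pipeline(config)

print("per-method means across patients")
for method in config.methods:
    sel = result.summaries[result.summaries.method == method]
    auc = sel["auc"].dropna()
    line = (f"  {method:10s} DLD {sel.dld_mean.mean():6.2f} mm"
            f"  SD {sel.sd_mean.mean():6.2f} mm" if sel.sd_mean.notna().any()
            else f"  {method:10s} DLD {sel.dld_mean.mean():6.2f} mm")
    if len(auc):
        line += f"  AUC {auc.mean():.3f}"
    print(line)

print("\noutcome prediction (concordance of the top lobe with the plan)")
for method, stats in result.prediction.items():
    c = result.confusions[method]
    print(f"  {method:10s} (tp={c.tp}, fp={c.fp}, tn={c.tn}, fn={c.fn})"
          f"  F1 = {stats.f1:.3f}")

print("\nSmaller DLD/SD means the method tracks the benchmark dipoles more "
      "closely; F1 summarises how well lobar concordance predicts a good "
      "outcome in this synthetic cohort.")
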