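"""Run the pipeline's validation experiments and report the numbers.

A condensed rerun of the checks in scripts/acceptance.py: oracle agreement
for the multinomial cell probabilities, closed-form and root-finder checks
of the two likelihood layers, recovery/calibration experiments, and
end-to-end fold recovery.  Sizes here are reduced for a quick narrative
run; scripts/acceptance.py runs the full versions.
"""

from pathlib import Path

import json

from herddens import experiments as E

OUT = Path(__file__).resolve().parents[1] / "results" / "validation"


def main() -> None:
    out = {}
    out["cell_probability_max_abs_error"] = E.cell_probability_oracle_error()
    print(f"cell probabilities vs quadrature: max error "
          f"{out['cell_probability_max_abs_error']:.2e}")

    rec = E.hds_parameter_recovery(n_rep=50, seed=2)
    print("parameter recovery (50 replicates):")
    print(rec.round(3).to_string(index=False))
    out["recovery_max_abs_bias_pct"] = float(rec["bias_pct"].abs().max())

    out["uniform_mle_relative_error"] = E.closed_form_uniform_check(2)
    print(f"closed-form uniform MLE check: {out['uniform_mle_relative_error']:.2e}")

    rate = E.size_bias_null_calibration(n_rep=400, n=200, seed=2)
    out["size_bias_null_rejection_rate"] = rate
    print(f"size-bias rule null rejection rate (threshold 0.15): {rate:.3f}")

    e2e = E.end_to_end_fold_recovery(n_rep=20, n_boot=200, seed=2)
    out.update({f"fold_{k}": v for k, v in e2e.items()})
    print(
        f"end-to-end park fold: mean {e2e['mean_fold']:.2f} "
        f"(truth {e2e['true_fold']:.2f}), CI coverage {e2e['coverage']:.2f}"
    )

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "validation.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {OUT}/validation.json")


if __name__ == "__main__":
    main()
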