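#!/usr/bin/env python
"""Generate the Italy-like parameter configuration and jittered variants.

Writes the deterministic default configuration (printed anchors fixed,
documented fixture values elsewhere) plus a few jittered copies for
robustness checks, all in the versioned YAML schema.
"""

from pathlib import Path

from flucea import default_italy_like, sample_parameter_set, save_parameter_set, validate

OUT = Path(__file__).resolve().parents[1] / "results" / "configs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    base = default_italy_like()
    assert validate(base) == []
    save_parameter_set(base, OUT / "italy_like_default.yaml")
    print(f"default config -> {OUT/'italy_like_default.yaml'}")
    print(f"  cohort {base.epi.cohort_size:,.0f}, attack rate {base.epi.attack_rate:.3f}, "
          f"WTP €{base.scenario.wtp_per_qaly:,.0f}")
    for seed in (1, 2, 3):
        jittered = sample_parameter_set(seed=seed, jitter=0.15)
        path = OUT / f"italy_like_jitter15_seed{seed}.yaml"
        save_parameter_set(jittered, path)
        print(f"jittered (seed {seed}) -> {path}")


if __name__ == "__main__":
    main()
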