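"""Generate the synthetic cold-acclimation study.

Produces the 5-genotype × 5-day grid of ground-truth condition
realizations (steady-state parameterizations) plus noisy steady-state
observations (10 % CV), and writes the parameter and observation tables
that the downstream analysis steps consume.

Run from the repository root:  python analysis/01_generate_study.py
"""

import json
from pathlib import Path

from coldcarb import generate_study
from coldcarb.io import write_observation_table, write_parameter_table

OUT = Path("results/study")
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    study = generate_study(n_genotypes=5, n_days=5, noise_cv=0.1, seed=SEED)
    write_parameter_table(study.realizations, OUT / "parameters.csv")
    write_observation_table(study.observations, OUT / "observations.csv")
    (OUT / "manifest.json").write_text(json.dumps(study.config, indent=1))

    pools = study.parameter_table()
    print(f"generated {len(study.realizations)} condition realizations "
          f"({len(study.genotypes)} genotypes x {len(study.days)} days), seed {SEED}")
    ss = [r.steady_state for r in study.realizations]
    print("steady-state pool ranges (umol/gDW): "
          + ", ".join(f"{n} {min(getattr(s, n) for s in ss):.2f}-"
                      f"{max(getattr(s, n) for s in ss):.2f}"
                      for n in ("F6P", "G6P", "Suc", "Frc", "Glc")))
    print(f"wrote {OUT}/parameters.csv ({pools.shape[0]} rows) and observations.csv")


if __name__ == "__main__":
    main()
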