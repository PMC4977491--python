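"""Filter by missingness, impute missing landmarks, and superimpose.

Mirror-imaging recovers bilateral landmarks with a present partner; the
thin-plate spline maps the remainder from the complete-specimen mean.
Since the data are simulated, imputation accuracy is measured against
the generating coordinates.  The completed configurations are aligned by
generalized Procrustes analysis, symmetrized, and written (with centroid
sizes) under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from craniomorph.gpa import symmetric_gpa
from craniomorph.impute import impute_dataset
from craniomorph.landmarks import (
    SymmetryScheme,
    filter_missingness,
    read_table,
    stacked_coords,
    write_table,
)
from craniomorph.synthetic import simulate_dataset, table1_design

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20261001


def main() -> None:
    for unit in ("cranium", "mandible"):
        sets = read_table(ROOT / "data" / f"{unit}.csv")
        scheme = SymmetryScheme.from_yaml(ROOT / "data" / f"{unit}_scheme.yaml")
        kept, excluded = filter_missingness(sets)
        complete = impute_dataset(kept, scheme)
        write_table(complete, ROOT / "data" / f"{unit}_complete.csv")

        # imputation accuracy against the generating coordinates
        _, truth = simulate_dataset(table1_design(unit, seed=SEED, missing_rate=0.05))
        errors = {"mirror": [], "tps": []}
        for i, (orig, comp) in enumerate(zip(sets, complete)):
            for j, method in comp.provenance.get("imputed", {}).items():
                err = np.linalg.norm(comp.coords[j] - truth.true_coords[i, j])
                errors[method].append(err)

        res = symmetric_gpa(stacked_coords(complete), scheme)
        pd.DataFrame(
            {
                "specimen_id": [s.specimen_id for s in complete],
                "group": [s.group for s in complete],
                "diet": [s.diet for s in complete],
                "centroid_size": res.centroid_sizes,
            }
        ).to_csv(ROOT / f"{unit}_centroid_sizes.csv", index=False)
        flat = res.aligned.reshape(len(complete), -1)
        cols = [f"{ax}{j + 1}" for j in range(res.k) for ax in "xyz"]
        aligned = pd.DataFrame(flat, columns=cols)
        aligned.insert(0, "specimen_id", [s.specimen_id for s in complete])
        aligned.to_csv(ROOT / f"{unit}_aligned.csv", index=False)

        print(f"{unit}: kept {len(kept)}, excluded {len(excluded)} (>=20% missing)")
        for method, errs in errors.items():
            if errs:
                print(
                    f"  {method}: {len(errs)} landmarks imputed, "
                    f"median error {np.median(errs):.2f} mm "
                    f"(generating landmark noise SD 2.0 mm per coordinate)"
                )
        print(
            f"  GPA converged in {res.iterations} iterations; "
            f"mean centroid size {res.centroid_sizes.mean():.1f} mm"
        )


if __name__ == "__main__":
    main()
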