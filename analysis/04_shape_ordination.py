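"""Shape ordination: total PCA, between-group PCA, axis shapes, allometry.

Between-group PCA projects every specimen onto the principal axes of the
group-means covariance; on data with a strongly displaced hunter-gatherer
group, bgPC1 should isolate it.  PC scores accounting for 95% of total
variance feed the downstream MANOVA and Mahalanobis analyses; allometry
is tested by regressing those scores on centroid size.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from craniomorph.gpa import symmetric_gpa
from craniomorph.landmarks import SymmetryScheme, read_table, stacked_coords
from craniomorph.ordination import (
    allometry_regression,
    between_group_pca,
    retain_for_variance,
    shape_at_score,
    total_pca,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for unit in ("cranium", "mandible"):
        sets = read_table(ROOT / "data" / f"{unit}_complete.csv")
        scheme = SymmetryScheme.from_yaml(ROOT / "data" / f"{unit}_scheme.yaml")
        res = symmetric_gpa(stacked_coords(sets), scheme)
        groups = np.array([s.group for s in sets])

        tot = total_pca(res.tangent_coords)
        scores = retain_for_variance(tot, 0.95)
        bg = between_group_pca(res.tangent_coords, groups)

        pd.DataFrame(
            {"axis1": bg.scores[:, 0], "axis2": bg.scores[:, 1], "group": groups}
        ).to_csv(ROOT / f"{unit}_bgpca_scores.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "eigenvalue": bg.eigenvalues,
                "between_group_fraction": bg.variance_fraction,
                "total_variance_fraction": bg.eigenvalues / bg.total_variance,
            }
        ).to_csv(ROOT / f"{unit}_bgpca_eigenvalues.tsv", sep="\t", index=False)

        # axis-extreme shapes for visualization of bgPC1 shape changes
        lo = shape_at_score(bg, 0, bg.scores[:, 0].min(), res.k)
        hi = shape_at_score(bg, 0, bg.scores[:, 0].max(), res.k)
        np.savetxt(ROOT / f"{unit}_bgpc1_low_shape.txt", lo, fmt="%.8f")
        np.savetxt(ROOT / f"{unit}_bgpc1_high_shape.txt", hi, fmt="%.8f")

        allo, allo_r2 = allometry_regression(scores, res.centroid_sizes)
        allo.assign(multivariate_r2=allo_r2).to_csv(
            ROOT / f"{unit}_allometry.tsv", sep="\t", index=False
        )

        meso = bg.scores[groups == "Mesolithic", 0]
        rest = bg.scores[groups != "Mesolithic", 0]
        separated = meso.min() > rest.max() or meso.max() < rest.min()
        print(
            f"{unit}: {scores.shape[1]} PCs retain 95% of variance; "
            f"bgPC1 carries {bg.variance_fraction[0]:.0%} of between-group "
            f"variance ({bg.eigenvalues[0] / bg.total_variance:.0%} of total)"
        )
        print(
            f"  hunter-gatherer group {'fully separated' if separated else 'overlaps'}"
            f" on bgPC1; multivariate allometric R^2 = {allo_r2:.3f}"
        )


if __name__ == "__main__":
    main()
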