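"""Per-gene hierarchical NB-GLM screen for scheme-by-generation trends.

Fits the full model (replicate-specific scheme and scheme x generation
effects tied through group-level means) and the reduced model without
interactions to every filtered gene, per sex; applies the likelihood-
ratio test with BH correction at the 0.001 level; classifies genes with
opposite group-level short/long trends and intersects them across
sexes.  Writes results/glm/{fits_F.tsv, fits_M.tsv, candidates.txt}.
"""

from pathlib import Path

import pandas as pd

from somnet import io as snio
from somnet.glm import classify_and_intersect
from somnet.normalize import split_counts
from somnet.workflows import glm_screen

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    counts = snio.read_counts_tsv(ROOT / "synthetic" / "counts.tsv")
    manifest = snio.read_manifest(ROOT / "synthetic" / "manifest.csv")
    out = ROOT / "glm"
    out.mkdir(parents=True, exist_ok=True)
    mat, regions = split_counts(counts)
    genic = mat[regions == "genic"]

    frames = {}
    for sex in ("F", "M"):
        kept = pd.read_csv(ROOT / "normalization" / f"kept_genes_{sex}.tsv", sep="\t")
        genes = [g for g in kept["feature_id"] if g in genic.index]
        frame = glm_screen(genic, manifest, sex, genes=genes, n_restarts=3, seed=1)
        frame.to_csv(out / f"fits_{sex}.tsv", sep="\t")
        frames[sex] = frame
        n_sig = int((frame["q"] < 0.001).sum())
        print(f"sex {sex}: {len(frame)} genes fitted, {n_sig} significant at q < 0.001")

    sets = classify_and_intersect(frames["F"], frames["M"], alpha=0.001)
    print(f"opposite-trend genes: F {len(sets['F'])}, M {len(sets['M'])}, "
          f"common to both sexes {len(sets['both'])}")
    (out / "candidates.txt").write_text("\n".join(sorted(sets["both"])) + "\n")


if __name__ == "__main__":
    main()
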