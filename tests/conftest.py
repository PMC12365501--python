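import numpy as np
import pandas as pd
import pytest

from tmtdiff import SimDesign, simulate_spikein
from tmtdiff.assay import FeatureAssay, SampleAnnotation


@pytest.fixture(scope="session")
def small_sim():
    """A small mixed DA/background simulation shared across tests."""
    design = SimDesign(n_proteins=60, background_fraction=0.7, seed=42)
    return simulate_spikein(design)


def random_psm_assay(rng, n_feat=8, n_prot=3, runs=("r1", "r2"),
                     channels=("c1", "c2", "c3"), missing=0.2):
    """Small random PSM assay used by IO and preprocessing tests."""
    feats, metas = [], []
    for i in range(n_feat):
        run = runs[int(rng.integers(len(runs)))]
        prot = f"prot{int(rng.integers(n_prot))}"
        fid = f"{run}:spec{i}"
        feats.append(fid)
        metas.append((prot, f"{prot}_pep{int(rng.integers(4))}",
                      f"spec{i}", run))
    samples = [f"{r}:{c}" for r in runs for c in channels]
    vals = rng.uniform(10.0, 1e6, size=(n_feat, len(samples)))
    vals[rng.random(vals.shape) < missing] = np.nan
    # structural: features observed only in their own run
    for i, (_, _, _, run) in enumerate(metas):
        for j, s in enumerate(samples):
            if not s.startswith(run + ":"):
                vals[i, j] = np.nan
    values = pd.DataFrame(vals, index=pd.Index(feats, name="feature_id"),
                          columns=samples)
    meta = pd.DataFrame(metas, index=values.index,
                        columns=["protein_id", "peptide_id", "spectrum_id",
                                 "run"])
    keep = values.notna().any(axis=1)
    return FeatureAssay(values=values[keep], feature_meta=meta[keep],
                        level="psm", log2=False)


def annotation_for(assay, reference=()):
    rows = []
    for s in assay.sample_ids:
        run, channel = s.split(":", 1)
        rows.append({"run": run, "channel": channel,
                     "mixture": "m1",
                     "condition": "A" if channel.endswith("1") else "B",
                     "bio_replicate": s, "tech_rep": "t1",
                     "is_reference": s in set(reference)})
    return SampleAnnotation.from_frame(pd.DataFrame(rows))
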