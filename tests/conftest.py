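import numpy as np
import pandas as pd
import pytest

from extractrank.io_tables import FeatureTable
from extractrank.synthetic_fixtures import FixtureSpec, generate_bundle


def make_table(area_rows, extracts, mz=None, rt=None, iin=None, ids=None):
    """Build a FeatureTable from a list of per-extract area rows."""
    n = len(area_rows)
    ids = ids if ids is not None else list(range(1, n + 1))
    index = pd.Index(ids, name="feature_id")
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(200.0, 800.0, n),
            "rt": rt if rt is not None else np.linspace(0.5, 7.5, n),
        },
        index=index,
    )
    features["iin_id"] = pd.array(iin if iin is not None else [pd.NA] * n, dtype="Int64")
    features["adduct"] = None
    areas = pd.DataFrame(area_rows, index=index, columns=extracts, dtype=float)
    return FeatureTable(features, areas)


def make_metadata(filenames, species=None, genus=None, family="Famexa", sample_type=None):
    n = len(filenames)
    species = species or [f"Spec species{i}" for i in range(n)]
    genus = genus or [s.split()[0] for s in species]
    return pd.DataFrame(
        {
            "filename": filenames,
            "species": species,
            "genus": genus,
            "family": [family] * n,
            "organ": ["roots"] * n,
            "sample_type": sample_type or ["sample"] * n,
        }
    )


@pytest.fixture(scope="session")
def outlier_bundle():
    """10 extracts, planted spectral outlier at index 9, 10% annotated."""
    return generate_bundle(
        FixtureSpec(
            n_extracts=10,
            n_features=100,
            fraction_specific=0.6,
            fraction_annotated=0.1,
            planted_outlier=9,
            novel_class_extracts=(0, 9),
            seed=42,
        )
    )
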