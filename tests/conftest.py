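import numpy as np
import pandas as pd
import pytest

from tauperf.atlas import load_atlas
from tauperf.core import CohortTable, Phase, SuvrMatrix


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def paper_like_study():
    """One paper-like synthetic study shared across tests (seed fixed)."""
    from tauperf.simulate import default_config, generate_study
    return generate_study(default_config("paper_like", seed=11))


def make_suvr_matrix(atlas, values, subject_ids, phase=Phase.EARLY):
    return SuvrMatrix(
        phase=phase,
        values=pd.DataFrame(
            values, index=pd.Index(subject_ids, name="subject_id"), columns=atlas.labels
        ),
    )


def make_cohort(subject_ids, groups, ages=None, sexes=None, **scores):
    n = len(subject_ids)
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "subject_id": subject_ids,
        "group": groups,
        "subgroup": groups,
        "age": ages if ages is not None else rng.uniform(60, 80, n).round(1),
        "sex": sexes if sexes is not None else ["F", "M"] * (n // 2) + ["F"] * (n % 2),
        "disease_duration_months": scores.get("duration", [24.0] * n),
        "pspr": scores.get("pspr", [np.nan] * n),
        "moca": scores.get("moca", [np.nan] * n),
        "seadl": scores.get("seadl", [np.nan] * n),
        "site": scores.get("site", ["training"] * n),
    })
    return CohortTable(df)
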