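import numpy as np
import pandas as pd
import pytest

from tractclass.cohort import (BUNDLES, HEMISPHERES, NODE_COLUMNS,
                               TISSUE_PROPERTIES)


def make_profile_table(values_by_subject: dict, missing: set = frozenset()):
    """Build a wide profile table by hand.

    ``values_by_subject`` maps subject_id → either a single 100-vector used
    for every (bundle, hemisphere, property) block, or a dict keyed by
    (bundle, tp, hemi) with 100-vectors.  Blocks listed in ``missing`` (as
    (subject_id, bundle, hemi) triples) are marked missing.
    """
    rows = []
    for sid, spec in values_by_subject.items():
        for b in BUNDLES:
            for h in HEMISPHERES:
                for tp in TISSUE_PROPERTIES:
                    if isinstance(spec, dict):
                        vals = np.asarray(spec[(b, tp, h)], dtype=float)
                    else:
                        vals = np.asarray(spec, dtype=float)
                    miss = (sid, b, h) in missing
                    row = {"subject_id": sid, "bundle": b, "hemisphere": h,
                           "tissue_property": tp, "missing": miss}
                    row.update({c: (np.nan if miss else v)
                                for c, v in zip(NODE_COLUMNS, vals)})
                    rows.append(row)
    return pd.DataFrame(rows)


def make_subjects(ids, labels, ages=None):
    n = len(ids)
    return pd.DataFrame({
        "id": list(ids),
        "age": ages if ages is not None else np.full(n, 60.0),
        "sex": np.zeros(n, dtype=int),
        "ethnicity": np.zeros(n, dtype=int),
        "tdi": np.zeros(n),
        "label": list(labels),
        "acuity_logmar": np.full(n, np.nan),
    })


@pytest.fixture
def profile_builder():
    return make_profile_table


@pytest.fixture
def subject_builder():
    return make_subjects
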