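import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stsm.casebase import AttributeSpec, CaseBase

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def build_case_base(times, events, check=True, arm=None, **attributes) -> CaseBase:
    """Small hand-built case base: ids c1..cn, one column per keyword attribute.

    Attribute kind is inferred: numeric if every non-missing value is a
    number, nominal otherwise.  Missing values are passed as None (nominal)
    or NaN (numeric).
    """
    n = len(times)
    schema = [AttributeSpec("id", "id"),
              AttributeSpec("time", "survival_time"),
              AttributeSpec("status", "survival_status")]
    data = {"id": [f"c{i + 1}" for i in range(n)],
            "time": np.asarray(times, dtype=float),
            "status": np.asarray(events, dtype=int)}
    if arm is not None:
        schema.append(AttributeSpec("arm", "arm"))
        data["arm"] = list(arm)
    for name, values in attributes.items():
        numeric = all(isinstance(v, (int, float)) for v in values)
        schema.append(AttributeSpec(name, "numeric" if numeric else "nominal"))
        if numeric:
            data[name] = np.asarray(values, dtype=float)
        else:
            data[name] = list(values)
    return CaseBase(schema, pd.DataFrame(data), check=check)


@pytest.fixture
def mixed_cb() -> CaseBase:
    """Six cases with one nominal and one numeric attribute plus missing values."""
    return build_case_base(
        times=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        events=[1, 1, 0, 1, 0, 1],
        sex=["m", "f", "m", None, "f", "m"],
        lab=[1.5, 2.5, float("nan"), 4.0, 2.0, 3.5],
    )
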