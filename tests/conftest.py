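import numpy as np
import pandas as pd
import pytest

from lsccpim.risk import pim_scores
from lsccpim.signature import find_optimal_cutpoint
from lsccpim.synth import CohortConfig, cohort_to_dataframe, generate_cohort


@pytest.fixture(scope="session")
def small_phantom():
    from lsccpim.synth import TextureParams, generate_tumor_phantom
    return generate_tumor_phantom(TextureParams(), (16, 16, 16), seed=7)


def make_replicate(seed: int, n: int = 96, beta_signature=None, beta_ast=None,
                   with_tki: bool = False):
    """One image-free simulated cohort with the downstream statuses the
    risk models need: signature status from a cut-point on the latent
    texture risk, AST status from the blood table.

    Returns (chemo DataFrame, statuses DataFrame) or, with ``with_tki``,
    (chemo, statuses, tki DataFrame).
    """
    kwargs = {}
    hz = {"beta_signature": float(np.log(2.45)), "beta_ast": float(np.log(3.66))}
    if beta_signature is not None:
        hz["beta_signature"] = beta_signature
    if beta_ast is not None:
        hz["beta_ast"] = beta_ast
    cfg = CohortConfig(n_chemo=n, n_tki=14 if with_tki else 0,
                       with_images=False, hazard_coefs=hz, seed=seed, **kwargs)
    df = cohort_to_dataframe(generate_cohort(cfg))
    chemo = df[df["arm"] == "chemo"].reset_index(drop=True)
    t = chemo["ttp_months"].to_numpy()
    e = chemo["ttp_event"].to_numpy(int)
    cut = find_optimal_cutpoint(chemo["latent_risk"].to_numpy(), t, e).cutoff
    statuses = pd.DataFrame({
        "signature": np.where(chemo["latent_risk"] <= cut, "normal", "risk"),
        "ast": np.where(chemo["ast"] > 40, "risk", "normal"),
    }, index=chemo.index)
    if with_tki:
        tki = df[df["arm"] == "tki"].reset_index(drop=True)
        return chemo, statuses, tki
    return chemo, statuses


def replicate_pim_scores(chemo, statuses):
    return pim_scores(statuses, ["signature", "ast"])["pim_score"].to_numpy()
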