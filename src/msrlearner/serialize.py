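"""JSON round-trip for fitted models.

The document stores the basis spec, per-block coefficients, membership model,
penalty, clipping bounds, seeds and the study-label mapping. Floats round-trip
bit-exactly (JSON shortest-repr encoding).
"""

from __future__ import annotations

import json

import numpy as np

from .basis import BasisSpec, StudyBasis
from .comparators import PooledFit, StudySpecificFit
from .estimator import CATEFit
from .nuisance import MembershipModel

SCHEMA_VERSION = 1


def fit_to_dict(fit, study_labels=None, seeds=None, clip_bounds=None,
                theta_cov=None, n_inference=None) -> dict:
    """Serialize a CATEFit / StudySpecificFit / PooledFit with a method tag."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "study_labels": list(study_labels) if study_labels is not None else None,
        "seeds": seeds,
        "clip_bounds": clip_bounds,
    }
    if isinstance(fit, CATEFit):
        doc.update(
            method="multi-study",
            beta=fit.beta.tolist(),
            basis=fit.basis.to_dict(),
            membership=fit.membership.to_dict() if fit.membership else None,
            penalty={"lam": fit.lam,
                     "P": None if fit.P is None else np.asarray(fit.P).tolist()},
            reparameterized=fit.reparameterized,
            plug_in_loss=fit.diagnostics.get("plug_in_loss"),
        )
    elif isinstance(fit, StudySpecificFit):
        doc.update(
            method="study-specific",
            betas=[b.tolist() for b in fit.betas],
            basis=fit.basis.to_dict(),
            membership=fit.membership.to_dict() if fit.membership else None,
            penalty={"lam": fit.lam, "P": None},
        )
    elif isinstance(fit, PooledFit):
        doc.update(
            method="pooled",
            beta=fit.beta.tolist(),
            basis=fit.basis.to_dict(),
            penalty={"lam": fit.lam, "P": None},
        )
    else:
        raise TypeError(f"cannot serialize {type(fit).__name__}")
    if theta_cov is not None:
        doc["inference"] = {"theta_cov": np.asarray(theta_cov).tolist(),
                            "n": int(n_inference)}
    return doc


def dict_to_fit(doc: dict):
    """Inverse of :func:`fit_to_dict`; returns the fit object (method tag decides type)."""
    method = doc["method"]
    memb = (MembershipModel.from_dict(doc["membership"])
            if doc.get("membership") else None)
    pen = doc.get("penalty", {"lam": 0.0, "P": None})
    P = None if pen["P"] is None else np.asarray(pen["P"], dtype=float)
    if method == "multi-study":
        fit = CATEFit(beta=np.asarray(doc["beta"], dtype=float),
                      basis=BasisSpec.from_dict(doc["basis"]),
                      membership=memb, lam=float(pen["lam"]), P=P,
                      reparameterized=doc.get("reparameterized", False),
                      diagnostics={"plug_in_loss": doc.get("plug_in_loss")})
        return fit
    if method == "study-specific":
        return StudySpecificFit(betas=[np.asarray(b, dtype=float) for b in doc["betas"]],
                                basis=BasisSpec.from_dict(doc["basis"]),
                                membership=memb, lam=float(pen["lam"]))
    if method == "pooled":
        return PooledFit(beta=np.asarray(doc["beta"], dtype=float),
                         basis=StudyBasis.from_dict(doc["basis"]),
                         lam=float(pen["lam"]))
    raise ValueError(f"unknown method tag {method!r}")


def save_fit(fit, path, **kw) -> None:
    with open(path, "w") as fh:
        json.dump(fit_to_dict(fit, **kw), fh)


def load_fit(path):
    with open(path) as fh:
        doc = json.load(fh)
    return dict_to_fit(doc), doc
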