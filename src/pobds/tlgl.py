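"""The bundled 18-gene T-LGL leukemia survival-signaling network.

Four candidate regulatory models form the uncertainty class used throughout
the experiments:

``true``
    the reduced T-LGL network as published;
``v2``
    the ``NOT Apoptosis`` factor removed from the sFas and GPCR rules
    (intermediate nodes — closest to the true network);
``v3``
    the ``NOT Apoptosis`` factor removed from the IAP and P2 rules;
``v4``
    the connective inside the BID rule's negation swapped (OR -> AND).

Each variant exists in a ``healthy`` form and a ``mutated`` form in which the
Apoptosis node is frozen at OFF (it no longer obeys its regulating function),
modeling the leukemic phenotype where programmed cell death cannot trigger.
"""

from __future__ import annotations

from importlib import resources

from .network import BooleanNetwork, parse_rules

__all__ = ["TLGL_VARIANTS", "TLGL_CLASSES", "tlgl_network", "tlgl_rule_text"]

TLGL_VARIANTS = ("true", "v2", "v3", "v4")
TLGL_CLASSES = ("healthy", "mutated")


def tlgl_rule_text(variant: str = "true", cls: str = "healthy") -> str:
    """Return the raw rule text for one of the bundled T-LGL fixtures."""
    if variant not in TLGL_VARIANTS:
        raise ValueError(f"unknown T-LGL variant {variant!r}; choose from {TLGL_VARIANTS}")
    if cls not in TLGL_CLASSES:
        raise ValueError(f"unknown class {cls!r}; choose from {TLGL_CLASSES}")
    name = f"tlgl_{variant}_{cls}.rules"
    return (resources.files("pobds.data") / name).read_text(encoding="utf-8")


def tlgl_network(variant: str = "true", cls: str = "healthy") -> BooleanNetwork:
    """Load one of the eight bundled T-LGL networks (4 variants x 2 classes)."""
    return parse_rules(tlgl_rule_text(variant, cls))
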