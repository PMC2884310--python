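"""Buildup factors: single-material GP evaluation and multi-layer composition.

The geometric-progression (GP) form gives the point-isotropic buildup factor
of one material as a function of optical depth x (mean free paths).  For a
stacked source-capsule / tissue path the two-region composition rule selects
its branch by the ordering of the layers' effective atomic numbers: a high-Z
layer in front of a low-Z layer (the usual encapsulated-source case) uses
the B2-interpolation branch; the reverse ordering adds a Compton-fraction
transfer term.  Paths with more than two layers are collapsed by a left fold
from the source side.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .physics_data import GPCoefficients, Material

__all__ = ["Layer", "LayerPath", "gp_buildup", "kalos_two_region",
           "effective_buildup", "THIN_LAYER_MFP"]

#: layers optically thinner than this (mfp) are dropped before composition;
#: mm-scale air channels fall far below it and would destabilise the ratio
#: term of the two-region rule.
THIN_LAYER_MFP = 1e-4

#: below this optical thickness of the first layer the two-region ratio
#: (B1(l1)-1)/(B2(l1)-1) is numerically indeterminate; the exact l1->0 limit
#: (buildup of layer 2 alone) is returned instead.
_L1_GUARD = 1e-6


@dataclass(frozen=True)
class Layer:
    """One material segment of a source-to-detector ray."""
    material: Material
    length_cm: float
    optical: float  # mu(E) * length, mfp


LayerPath = Sequence[Layer]


def gp_buildup(coeffs: GPCoefficients, x: float) -> float:
    """GP buildup factor at optical depth ``x`` (mfp).

    B(x) = 1 + (b-1)(K^x - 1)/(K - 1), with the linear branch
    B = 1 + (b-1)x when K(x) is within 1e-9 of unity.  B(0) = 1 and the
    result is clamped to >= 1 (scatter can only add dose).
    """
    if x < 0:
        raise ValueError(f"optical depth must be >= 0, got {x}")
    if x == 0.0:
        return 1.0
    b, c, a, x_k, d = coeffs.b, coeffs.c, coeffs.a, coeffs.x_K, coeffs.d
    tanh_m2 = math.tanh(-2.0)
    k = c * x ** a + d * (math.tanh(x / x_k - 2.0) - tanh_m2) / (1.0 - tanh_m2)
    if abs(k - 1.0) < 1e-9:
        bu = 1.0 + (b - 1.0) * x
    else:
        bu = 1.0 + (b - 1.0) * (k ** x - 1.0) / (k - 1.0)
    return bu if bu > 1.0 else 1.0


def kalos_two_region(mat1: Material, l1: float, mat2: Material, l2: float,
                     e_mev: float) -> float:
    """Effective buildup for a two-layer path, source-side layer first.

    Branch selection by effective atomic number: Z1 > Z2 uses
    B = B2(l2) + [B1(l1)-1]/[B2(l1)-1] * [B2(l1+l2) - B2(l2)];
    Z2 > Z1 adds the Compton-fraction transfer term with the exp(-1.7 l2)
    weighting; equal Z collapses to the single-material factor at l1+l2.
    """
    if l1 < 0 or l2 < 0:
        raise ValueError("optical thicknesses must be >= 0")
    gp2 = mat2.gp_at(e_mev)
    if l1 < _L1_GUARD:
        return gp_buildup(gp2, l2)
    gp1 = mat1.gp_at(e_mev)
    z1, z2 = mat1.effective_Z, mat2.effective_Z
    if z1 == z2:
        return gp_buildup(gp2, l1 + l2)
    b1_l1 = gp_buildup(gp1, l1)
    b2_l1 = gp_buildup(gp2, l1)
    b2_l2 = gp_buildup(gp2, l2)
    b2_tot = gp_buildup(gp2, l1 + l2)
    denom = b2_l1 - 1.0
    if denom <= 1e-12:
        return b2_l2
    ratio = (b1_l1 - 1.0) / denom
    if z1 > z2:
        bu = b2_l2 + ratio * (b2_tot - b2_l2)
    else:
        fc1 = mat1.compton_fraction_at(e_mev)
        fc2 = mat2.compton_fraction_at(e_mev)
        bu = b2_l2 + (b2_tot - b2_l2) * (
            ratio * math.exp(-1.7 * l2)
            + (fc1 / fc2) * (1.0 - math.exp(-l2))
        )
    return bu if bu > 1.0 else 1.0


def _merge(layers: list) -> list:
    """Drop optically thin layers, then merge adjacent same-material runs."""
    kept = [l for l in layers
            if l.optical >= THIN_LAYER_MFP and not l.material.is_vacuum]
    merged: list = []
    for l in kept:
        if merged and merged[-1].material == l.material:
            prev = merged[-1]
            merged[-1] = Layer(prev.material, prev.length_cm + l.length_cm,
                               prev.optical + l.optical)
        else:
            merged.append(l)
    return merged


def effective_buildup(path: LayerPath, e_mev: float) -> float:
    """Effective buildup factor for an ordered source-to-detector path.

    Single layer: GP factor.  Two layers: two-region rule.  More: left fold
    from the source side — the two innermost layers are combined, the pair is
    then treated as a pseudo-layer of the outer material carrying the summed
    optical thickness, and the running factor is corrected by the ratio of
    the combined buildup to the pseudo-layer's own GP factor.
    """
    layers = _merge(list(path))
    if not layers:
        return 1.0
    if len(layers) == 1:
        return gp_buildup(layers[0].material.gp_at(e_mev), layers[0].optical)
    acc = kalos_two_region(layers[0].material, layers[0].optical,
                           layers[1].material, layers[1].optical, e_mev)
    cur_mat = layers[1].material
    cur_l = layers[0].optical + layers[1].optical
    for nxt in layers[2:]:
        pair = kalos_two_region(cur_mat, cur_l, nxt.material, nxt.optical, e_mev)
        base = gp_buildup(cur_mat.gp_at(e_mev), cur_l)
        acc = pair * (acc / base)
        cur_mat = nxt.material
        cur_l += nxt.optical
    return acc if acc > 1.0 else 1.0
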