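"""Independent reference evaluations used to cross-check the engine.

These deliberately share no code with the package: the data files are
re-parsed here by hand and the buildup / kerma formulas are evaluated
directly, so a test comparing both routes checks the implementation, not
itself.
"""
import math
from importlib import resources

_J_PER_MEV = 1.602e-13


def _read_rows(fname):
    text = resources.files("brachykernel.data").joinpath(fname).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(x) for x in line.split("\t")])
    return rows


def material_rows(key):
    return _read_rows(f"material_{key}.tsv")


def absorber_rows(key):
    return _read_rows(f"absorber_{key}.tsv")


def spectrum_rows(key):
    return _read_rows(f"spectrum_{key}.tsv")


def interp_loglog(e, rows, col):
    for r0, r1 in zip(rows, rows[1:]):
        if r0[0] <= e <= r1[0]:
            t = (math.log(e) - math.log(r0[0])) / (math.log(r1[0]) - math.log(r0[0]))
            return math.exp((1 - t) * math.log(r0[col]) + t * math.log(r1[col]))
    raise ValueError(f"energy {e} out of range")


def interp_loglin(e, rows, col):
    for r0, r1 in zip(rows, rows[1:]):
        if r0[0] <= e <= r1[0]:
            t = (math.log(e) - math.log(r0[0])) / (math.log(r1[0]) - math.log(r0[0]))
            return (1 - t) * r0[col] + t * r1[col]
    raise ValueError(f"energy {e} out of range")


def gp_factor(rows, e, x):
    """Direct evaluation of the GP buildup form from a material table."""
    b = interp_loglin(e, rows, 3)
    c = interp_loglin(e, rows, 4)
    a = interp_loglin(e, rows, 5)
    xk = interp_loglin(e, rows, 6)
    d = interp_loglin(e, rows, 7)
    if x == 0:
        return 1.0
    th = math.tanh(-2.0)
    k = c * x ** a + d * (math.tanh(x / xk - 2.0) - th) / (1.0 - th)
    if abs(k - 1.0) < 1e-9:
        bu = 1.0 + (b - 1.0) * x
    else:
        bu = 1.0 + (b - 1.0) * (k ** x - 1.0) / (k - 1.0)
    return max(bu, 1.0)


def two_region_factor(rows1, z1, rows2, z2, l1, l2, e):
    """Direct evaluation of the two-region composition rule."""
    if l1 < 1e-6:
        return gp_factor(rows2, e, l2)
    b1_l1 = gp_factor(rows1, e, l1)
    b2_l1 = gp_factor(rows2, e, l1)
    b2_l2 = gp_factor(rows2, e, l2)
    b2_tot = gp_factor(rows2, e, l1 + l2)
    if z1 == z2:
        return gp_factor(rows2, e, l1 + l2)
    ratio = (b1_l1 - 1.0) / (b2_l1 - 1.0)
    if z1 > z2:
        return max(b2_l2 + ratio * (b2_tot - b2_l2), 1.0)
    fc1 = interp_loglin(e, rows1, 2)
    fc2 = interp_loglin(e, rows2, 2)
    return max(b2_l2 + (b2_tot - b2_l2) * (ratio * math.exp(-1.7 * l2)
               + fc1 / fc2 * (1.0 - math.exp(-l2))), 1.0)


def fold_factor(layer_specs, e):
    """Step-by-step left fold of (rows, Z, l) layers, source to detector."""
    if len(layer_specs) == 1:
        rows, _, l = layer_specs[0]
        return gp_factor(rows, e, l)
    (r1, z1, l1), (r2, z2, l2) = layer_specs[0], layer_specs[1]
    acc = two_region_factor(r1, z1, r2, z2, l1, l2, e)
    cur_rows, cur_z, cur_l = r2, z2, l1 + l2
    for rows, z, l in layer_specs[2:]:
        pair = two_region_factor(cur_rows, cur_z, rows, z, cur_l, l, e)
        acc = pair * (acc / gp_factor(cur_rows, e, cur_l))
        cur_rows, cur_z, cur_l = rows, z, cur_l + l
    return max(acc, 1.0)


def bare_point_dose_water(activity_bq, r_cm, nuclide="Cs-137"):
    """Closed-form dose rate (cGy/h) of a bare point source in water."""
    w = material_rows("water")
    aw = absorber_rows("water")
    total = 0.0
    for e, p in spectrum_rows(f"{nuclide}"):
        mu = interp_loglog(e, w, 1)
        b = gp_factor(w, e, mu * r_cm)
        psi = activity_bq * p * e * math.exp(-mu * r_cm) / (4 * math.pi * r_cm ** 2)
        total += psi * b * interp_loglog(e, aw, 1)
    return total * _J_PER_MEV * 1e3 * 3600 * 100


def kerma_constant(nuclide):
    """Spectrum-weighted unfiltered air-kerma rate constant, uGy h^-1 m^2/Bq."""
    aa = absorber_rows("air")
    tot = sum(p * e * interp_loglog(e, aa, 1) for e, p in spectrum_rows(nuclide))
    return tot * _J_PER_MEV * 1e3 * 3600 / (4 * math.pi * 1e4) * 1e6
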