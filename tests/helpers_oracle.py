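"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive the model from first principles with plain
Python loops and inline formulas, independent of the package's vectorized
evaluation path.
"""

import itertools

ALTERNATING_TRIPLES = (("pMad", "Tin", "pMad"), ("Tin", "pMad", "Tin"))


def sphere_overlap(gap: float, radius: float) -> float:
    """Normalized lens volume of two equal spheres (inline closed form)."""
    if radius <= 0 or gap >= 2 * radius:
        return 0.0
    return (4 * radius + gap) * (2 * radius - gap) ** 2 / (16 * radius**3)


def _gap_radius(design, i, params) -> float:
    """Interaction radius for the gap between sites i and i+1."""
    left, right = design.sites[i], design.sites[i + 1]
    tins = [s for s in (left, right) if s.tf_name == "Tin"]
    if not tins:
        return params.r_antisense
    antisense = any(s.orientation == "antisense" for s in tins)
    return params.r_antisense if antisense else params.r_sense


def brute_force_states(design, params, variant, tissue_rule=None):
    """Yield (occupancy, weight, active) for every one of the 2^n states."""
    n = design.n_sites
    for bits in itertools.product((0, 1), repeat=n):
        weight = 1.0
        for b, site in zip(bits, design.sites):
            if b:
                weight *= params.a0 if site.tf_name == "pMad" else params.b0
        active = False
        for i in range(n - 1):
            left, right = design.sites[i], design.sites[i + 1]
            hetero = {left.tf_name, right.tf_name} == {"pMad", "Tin"}
            if bits[i] and bits[i + 1] and hetero:
                om = sphere_overlap(design.spacings[i], _gap_radius(design, i, params))
                weight *= 1.0 + (params.q1 - 1.0) * om
                if variant == "pairs_only" and om > 0:
                    active = True
        if variant == "higher_order":
            for i in range(n - 2):
                trip = tuple(s.tf_name for s in design.sites[i : i + 3])
                if trip in ALTERNATING_TRIPLES and bits[i] and bits[i + 1] and bits[i + 2]:
                    om1 = sphere_overlap(design.spacings[i], _gap_radius(design, i, params))
                    om2 = sphere_overlap(
                        design.spacings[i + 1], _gap_radius(design, i + 1, params)
                    )
                    weight *= 1.0 + (params.q2 - 1.0) * min(om1, om2)
                    if (
                        tissue_rule is not None
                        and trip == tissue_rule.minimal_unit
                        and om1 > 0
                        and om2 > 0
                    ):
                        active = True
        yield bits, weight, active


def brute_force_partition(design, params, variant):
    return sum(w for _, w, _ in brute_force_states(design, params, variant))


def brute_force_activation(design, params, tissue_rule, variant):
    z = 0.0
    active_mass = 0.0
    for _, w, active in brute_force_states(design, params, variant, tissue_rule):
        z += w
        if active:
            active_mass += w
    return active_mass / z


def random_design(rng, n_sites, name="rand"):
    """Random pMad/Tin arrangement with random orientations and gaps."""
    from crmgrammar.motifs import CRMDesign, Site
    from crmgrammar.occupancy import PMAD_MOTIF, TIN_MOTIF

    sites = []
    for _ in range(n_sites):
        tf = "pMad" if rng.random() < 0.5 else "Tin"
        seq = PMAD_MOTIF if tf == "pMad" else TIN_MOTIF
        orient = "sense" if rng.random() < 0.5 else "antisense"
        sites.append(Site(tf, seq, orient))
    gaps = tuple(int(g) for g in rng.integers(0, 11, size=max(n_sites - 1, 0)))
    return CRMDesign(name, tuple(sites), gaps)


def random_params(rng):
    from crmgrammar.occupancy import ModelParams

    return ModelParams(
        q1=float(10 ** rng.uniform(0, 2)),
        q2=float(10 ** rng.uniform(0, 2)),
        r_sense=float(rng.uniform(0, 6)),
        r_antisense=float(rng.uniform(0, 6)),
        a0=float(rng.uniform(0.3, 3.0)),
        b0=float(rng.uniform(0.3, 3.0)),
    )
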