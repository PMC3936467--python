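"""Independent brute-force oracles shared by the test modules."""

import itertools

import numpy as np


def flood_fill_components(mask, neighborhood):
    """Brute-force BFS connected components; returns a set of frozensets
    of voxel-index tuples. Written independently of scipy.ndimage.label."""
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=3) if any(o)]
    if neighborhood == 6:
        offsets = [o for o in offsets if sum(map(abs, o)) == 1]
    elif neighborhood == 18:
        offsets = [o for o in offsets if sum(map(abs, o)) <= 2]
    active = {tuple(v) for v in np.argwhere(mask)}
    seen, components = set(), []
    for start in sorted(active):
        if start in seen:
            continue
        queue, comp = [start], set()
        seen.add(start)
        while queue:
            v = queue.pop()
            comp.add(v)
            for o in offsets:
                nb = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if nb in active and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        components.append(frozenset(comp))
    return set(components)
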