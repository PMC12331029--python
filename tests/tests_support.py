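"""Helpers shared between test modules."""
import numpy as np

from depthpop.core import RateMap


def map_from_values(values, occupancy=None, min_occ=0.2):
    """Wrap a 1-D array of per-bin rates into a RateMap with full occupancy."""
    values = np.asarray(values, float)
    occ = (np.ones_like(values) if occupancy is None
           else np.asarray(occupancy, float))
    edges = (np.arange(values.size + 1, dtype=float),)
    normalized = np.where(occ >= min_occ, values, np.nan)
    return RateMap(bin_edges=edges, activity=values * occ, occupancy=occ,
                   normalized=normalized, min_occupancy=min_occ)
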