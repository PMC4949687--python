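"""Vertex-area overlap between a reading-activation mask and map masks.

Builds three masks on a spherical cortex — a reading activation and two
topological maps — and reports what percentage of the reading activation
area falls inside each map and inside their union, overall and per region.
"""

import numpy as np

from cortimap import (
    RegionPartition,
    geodesic_distances,
    make_icosphere,
    multimap_report,
)

mesh = make_icosphere(3, 50.0)
areas = mesh.vertex_areas()
d0 = geodesic_distances(mesh, 0)
d_far = geodesic_distances(mesh, 300)

reading = set(np.flatnonzero(d0 <= 30.0).tolist())
retinotopy = set(np.flatnonzero(d0 <= 22.0).tolist())
tonotopy = set(np.flatnonzero(d_far <= 25.0).tolist())

partition = RegionPartition(regions={
    "posterior": set(np.flatnonzero(d0 <= 15.0).tolist()),
    "anterior": set(np.flatnonzero((d0 > 15.0) & (d0 <= 40.0)).tolist()),
})

report = multimap_report(reading, {"retinotopy": retinotopy, "tonotopy": tonotopy},
                         areas, partition)
print(report.round(1).to_string())
# percent_overlap is overlap area / reading area (the activation is the
# denominator); the union row bounds every single-map row from above.
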