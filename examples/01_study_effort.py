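"""Load the packaged Jersey grass-snake survey frame and summarise effort.

The fixture holds the 19 site-year transects (2014-2015). The totals below
are the study-wide accounting: artificial cover object (ACO) checks are
visits x ACOs summed over site-years, kilometres are visits x transect
length, and naive occupancy is the fraction of site-years with at least one
snake seen — an underestimate of true occupancy whenever detection is
imperfect.
"""

import occumix as ox

design, covariates = ox.load_fixture()
summary = ox.summarize_effort(design)

print(f"site-years:          {design.n_sites}")
print(f"total surveys:       {summary.total_surveys}")
print(f"total ACO checks:    {summary.total_aco_checks}")
print(f"total km walked:     {summary.total_km:.1f}")
print(f"mean ACOs per site:  {summary.mean_acos_per_site:.0f}")
print(f"mean transect (km):  {summary.mean_transect_km:.2f}")
print(f"naive occupancy:     {summary.naive_occupancy:.2f}")
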