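"""Two-component isotopic hydrograph separation of the storm response.

Solves the delta-2H mass balance f_new = (c_stream - c_old) / (c_new -
c_old) per day, using the pre-event stream mean as the old-water endmember
and the precipitation signature as the new-water endmember, then summarises
the event response.
"""

from microcq import (
    SimulationConfig,
    d_excess,
    event_response_summary,
    hydrograph_separation,
    simulate_campaign,
    two_component_fraction,
)

# the observed worked example: stream -52.1 permil at peak, old water -53.9,
# event precipitation -38.7
f = two_component_fraction(-52.1, -53.9, -38.7)
print("new-water fraction at peak from observed endmembers: %.4f" % f)
print("=> old water share %.1f%%" % (100 * (1 - f)))

sim = simulate_campaign(SimulationConfig(rng_seed=1))
config = SimulationConfig(rng_seed=1)
mixing = hydrograph_separation(
    sim["isotopes"], sim["hydro"], c_new=config.delta_new,
    preevent_dates=sim["hydro"].index[:4],
)
summary = event_response_summary(sim["hydro"], mixing, sim["hydro"].index[:4])
for key, value in summary.items():
    print(f"{key}: {value}")

print("d-excess on the pre-event mean: %.1f permil" % d_excess(-53.9, -8.0))

# Even though discharge rises >600%, the stream's isotope signature barely
# moves: ~88% of peak flow is water already stored in the catchment, and
# only ~0.2 CMS of the 1.8 CMS peak is new storm water.
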