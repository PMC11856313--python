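"""Update the infection-rate estimate and derive mask demand.

The allocation decision each morning uses the previous day's posterior
mean of the infection rate.  With a normal-normal conjugate model,
precisions add and the posterior mean is the precision-weighted average
of the prior (observations from other areas) and the local sample
observation.  Day 1 uses the case's recorded numbers: local observation
1.401 (sd 0.683) against an other-area prior of 3.311.
"""

from gabc import demand_units, posterior_mean

prior_mean, prior_sd = 3.311, 1.0   # other-area observations
obs_mean, obs_sd = 1.401, 0.683     # local day-1 sample

post = posterior_mean(prior_mean, prior_sd, obs_mean, obs_sd)
print(f"posterior infection rate: mean {post.mean:.3f}, sd {post.variance**0.5:.3f}")
print("(pulled toward the local observation, which has the higher precision)")

# The mapping from rate to daily case counts is area-specific; with the
# case's implied day-1 count of 772 infections:
cases = 772
print(f"day-1 demand at 10 masks per case: {demand_units(cases):,.0f} masks")
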