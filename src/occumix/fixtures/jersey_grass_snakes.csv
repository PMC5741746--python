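# Jersey grass snake (Natrix helvetica) transect survey design, 2014-2015.
# One row per site-year ("site"); 19 site-years across 14 sites, four habitat
# classes. Columns: number of surveys (n_visits), artificial cover objects
# checked per visit (acos), transect length in km, and the naive
# detected/not-detected status of the site-year (1 = at least one snake seen).
# The p/psi/lam columns are the published transect-specific estimates of
# per-survey detection, occupancy and latent abundance with 95% interval
# endpoints; they are regression anchors, not model inputs.
# Data notes:
#  * n_visits_printed preserves the source table's visit counts, which sum
#    to 134 and contradict the study-wide totals (132 surveys, 12,335 ACO
#    checks, 613 km). Setting J-2015 to 6 visits (n_visits) reconciles all
#    three totals simultaneously; that single minimal correction is used.
#  * detected flags are derived from the lam interval lower bounds: the
#    empirical-Bayes abundance posterior has zero mass below the maximum
#    observed count, so lam_lo >= 1 iff the site-year had a detection.
#    Exactly 11 of 19 site-years are detected (naive occupancy 0.58).
site,year,habitat,area_ha,n_visits,n_visits_printed,acos,transect_km,detected,p_est,p_lo,p_hi,psi_est,psi_lo,psi_hi,lam_est,lam_lo,lam_hi
A,2015,scrub,8.10,3,3,39,2.91,0,0.23,0.13,0.36,0.69,0.33,0.91,0.67,0,3
B,2014,scrub,75.91,8,8,90,6.07,0,0.32,0.22,0.44,0.82,0.50,0.96,0.47,0,2
C,2014,dune grassland,36.99,8,8,117,6.40,1,0.38,0.27,0.50,0.83,0.51,0.96,2.94,2,5
C,2015,dune grassland,36.50,6,6,238,10.53,1,0.64,0.43,0.81,0.89,0.64,0.97,7.94,5,11
D,2014,scrub,23.19,8,8,72,3.41,0,0.29,0.19,0.41,0.72,0.36,0.92,0.27,0,2
E,2014,amenity grassland,29.63,8,8,34,1.12,0,0.22,0.13,0.36,0.46,0.16,0.80,0.09,0,1
F,2014,dune grassland,65.72,8,8,195,8.77,1,0.55,0.38,0.71,0.87,0.59,0.97,5.44,4,8
F,2015,dune grassland,65.64,6,6,436,19.10,1,0.92,0.62,0.99,0.94,0.76,0.99,8.06,5,12
G,2014,scrub,38.81,8,8,81,4.19,1,0.30,0.20,0.43,0.76,0.41,0.94,1.33,1,3
H,2014,rough grassland,29.53,8,8,45,4.51,0,0.24,0.14,0.37,0.78,0.43,0.94,0.35,0,2
I,2015,amenity grassland,3.89,4,4,51,1.76,0,0.25,0.15,0.38,0.58,0.23,0.86,0.33,0,2
J,2014,scrub,10.48,8,8,60,2.20,1,0.26,0.17,0.39,0.63,0.27,0.89,1.54,1,3
J,2015,scrub,10.48,6,8,110,4.86,1,0.36,0.25,0.48,0.79,0.45,0.95,4.14,2,7
K,2014,scrub,15.77,8,8,42,2.80,0,0.23,0.14,0.37,0.68,0.32,0.91,0.22,0,1
L,2014,scrub,37.54,8,8,90,6.07,1,0.32,0.22,0.44,0.82,0.50,0.96,1.79,1,4
L,2015,scrub,3.61,6,6,46,1.46,1,0.24,0.14,0.37,0.53,0.19,0.84,1.18,1,2
M,2014,rough grassland,1.01,8,8,6,0.28,1,0.18,0.09,0.33,0.18,0.04,0.50,1.08,1,2
M,2015,rough grassland,1.01,5,5,18,0.44,1,0.20,0.10,0.34,0.25,0.07,0.61,1.07,1,2
N,2014,amenity grassland,36.06,8,8,36,1.62,0,0.22,0.13,0.36,0.56,0.21,0.85,0.13,0,1
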