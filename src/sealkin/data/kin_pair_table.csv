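plod,birth_year_i,age_i,birth_year_j,birth_gap,mtdna,rel_prob_hsp
42,2008,0,2011,3,M,1.00
47,2006,2,2011,5,P,1.00
50,2015,0,2017,2,M,1.00
51,2004,0,2009,5,P,1.00
56,1997,7,2008,11,M,0.80
59,2015,0,2015,0,P,1.00
63,2007,0,2020,13,P,1.00
63,1993,13,2005,12,P,0.57
63,2004,4,2008,4,P,1.00
64,2012,1,2015,3,M,1.00
70,2002,0,2012,10,P,1.00
72,2010,1,2010,0,P,1.00
74,2009,1,2011,2,M,1.00
76,2012,1,2019,6,P,1.00
80,1999,6,2010,11,P,0.90
81,2009,0,2017,8,P,1.00
83,2012,0,2014,2,M,1.00
83,2004,0,2009,5,M,1.00
86,1998,14,2009,11,P,0.90
87,1999,12,2005,6,P,1.00
88,2006,0,2012,6,P,1.00
109,2008,4,2014,6,P,1.00
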