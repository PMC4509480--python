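state	region	latitude	n_subjects
Perlis	North	6.394462	7
Kedah	North	5.329221	
Pulau Pinang	North	5.329221	
Perak	North	4.619018	5
Kelantan (Kota Bharu)	North	5.715314	56
Kelantan (Jeli)	North	5.497056	74
Terengganu	North	5.325092	4
Pahang (Pekan)	Centre	3.492092	51
Selangor	Centre	2.842971	98
Negeri Sembilan	South	2.553541	9
Melaka	South	2.203281	5
Johor	South	1.461662	4
Singapore (Malay)	South	1.287043	89
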