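column	type	min	max	categories	description
patient_id	str			 	opaque unique identifier
age	float	0	120		age in years
sex	category			male|female
bmi	float	5	100		body mass index, kg/m^2
smoking	category			current|ex|never
disease_duration	float	0	120		CRS duration, years
n_ess	int	0			endoscopic sinus surgeries, ever
n_scs_past_year	int	0			systemic corticosteroid courses, past year
asthma	bool				physician/self-reported asthma
allergy	bool
nerd	bool				NSAID-exacerbated respiratory disease
snot22	int	0	110		SNOT-22 total score
lund_mackay	int	0	24		Lund-Mackay CT score
vas_tss	float	0	100		VAS total sinus symptoms, mm
vas_nb	float	0	100		VAS nasal blockage, mm
vas_los	float	0	100		VAS loss of smell, mm
nps	int	0	8		nasal polyp score, 0-4 per side
bec	float	0			blood eosinophil count, cells/uL
ige	float	0			serum total IgE, IU/mL
biologic_initiated	bool				biologic started at index date
incs	bool				intranasal corticosteroid use
ics	bool				inhaled corticosteroid use
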