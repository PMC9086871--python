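kind	name	state	county
state	Alabama	AL
state	Alaska	AK
state	Arizona	AZ
state	Arkansas	AR
state	California	CA
state	Colorado	CO
state	Connecticut	CT
state	Delaware	DE
state	District of Columbia	DC
state	Florida	FL
state	Georgia	GA
state	Hawaii	HI
state	Idaho	ID
state	Illinois	IL
state	Indiana	IN
state	Iowa	IA
state	Kansas	KS
state	Kentucky	KY
state	Louisiana	LA
state	Maine	ME
state	Maryland	MD
state	Massachusetts	MA
state	Michigan	MI
state	Minnesota	MN
state	Mississippi	MS
state	Missouri	MO
state	Montana	MT
state	Nebraska	NE
state	Nevada	NV
state	New Hampshire	NH
state	New Jersey	NJ
state	New Mexico	NM
state	New York	NY
state	North Carolina	NC
state	North Dakota	ND
state	Ohio	OH
state	Oklahoma	OK
state	Oregon	OR
state	Pennsylvania	PA
state	Rhode Island	RI
state	South Carolina	SC
state	South Dakota	SD
state	Tennessee	TN
state	Texas	TX
state	Utah	UT
state	Vermont	VT
state	Virginia	VA
state	Washington	WA
state	West Virginia	WV
state	Wisconsin	WI
state	Wyoming	WY
county	Maricopa County	AZ
county	Alameda County	CA
county	Los Angeles County	CA
county	Orange County	CA
county	Riverside County	CA
county	Sacramento County	CA
county	San Bernardino County	CA
county	San Diego County	CA
county	San Francisco County	CA
county	San Mateo County	CA
county	District of Columbia	DC
county	Broward County	FL
county	Duval County	FL
county	Hillsborough County	FL
county	Miami-Dade County	FL
county	Orange County	FL
county	Palm Beach County	FL
county	Pinellas County	FL
county	Cobb County	GA
county	DeKalb County	GA
county	Fulton County	GA
county	Gwinnett County	GA
county	Cook County	IL
county	Sangamon County	IL
county	Marion County	IN
county	East Baton Rouge Parish	LA
county	Orleans Parish	LA
county	Baltimore City	MD
county	Montgomery County	MD
county	Prince George's County	MD
county	Hampden County	MA
county	Suffolk County	MA
county	Wayne County	MI
county	Greene County	MO
county	Clark County	NV
county	Essex County	NJ
county	Hudson County	NJ
county	Bernalillo County	NM
county	Bronx County	NY
county	Kings County	NY
county	New York County	NY
county	Queens County	NY
county	Mecklenburg County	NC
county	Cuyahoga County	OH
county	Franklin County	OH
county	Hamilton County	OH
county	Multnomah County	OR
county	Philadelphia County	PA
county	Shelby County	TN
county	Bexar County	TX
county	Dallas County	TX
county	Harris County	TX
county	Tarrant County	TX
county	Travis County	TX
county	King County	WA
county	Milwaukee County	WI
city	Phoenix	AZ	Maricopa County
city	Oakland	CA	Alameda County
city	Los Angeles	CA	Los Angeles County
city	Long Beach	CA	Los Angeles County
city	Anaheim	CA	Orange County
city	Riverside	CA	Riverside County
city	Sacramento	CA	Sacramento County
city	San Diego	CA	San Diego County
city	San Francisco	CA	San Francisco County
city	Washington	DC	District of Columbia
city	Fort Lauderdale	FL	Broward County
city	Jacksonville	FL	Duval County
city	Tampa	FL	Hillsborough County
city	Miami	FL	Miami-Dade County
city	Orlando	FL	Orange County
city	Atlanta	GA	Fulton County
city	Chicago	IL	Cook County
city	Springfield	IL	Sangamon County
city	Indianapolis	IN	Marion County
city	Baton Rouge	LA	East Baton Rouge Parish
city	New Orleans	LA	Orleans Parish
city	Baltimore	MD	Baltimore City
city	Boston	MA	Suffolk County
city	Springfield	MA	Hampden County
city	Detroit	MI	Wayne County
city	Springfield	MO	Greene County
city	Las Vegas	NV	Clark County
city	Newark	NJ	Essex County
city	Jersey City	NJ	Hudson County
city	Albuquerque	NM	Bernalillo County
city	New York	NY	New York County
city	New York City	NY	New York County
city	Manhattan	NY	New York County
city	Brooklyn	NY	Kings County
city	Queens	NY	Queens County
city	The Bronx	NY	Bronx County
city	Charlotte	NC	Mecklenburg County
city	Cleveland	OH	Cuyahoga County
city	Columbus	OH	Franklin County
city	Cincinnati	OH	Hamilton County
city	Portland	OR	Multnomah County
city	Philadelphia	PA	Philadelphia County
city	Memphis	TN	Shelby County
city	San Antonio	TX	Bexar County
city	Dallas	TX	Dallas County
city	Houston	TX	Harris County
city	Fort Worth	TX	Tarrant County
city	Austin	TX	Travis County
city	Seattle	WA	King County
city	Milwaukee	WI	Milwaukee County
alias	nyc	NY	New York County
alias	philly	PA	Philadelphia County
alias	atl	GA	Fulton County
alias	vegas	NV	Clark County
alias	nola	LA	Orleans Parish
alias	sf	CA	San Francisco County
alias	chitown	IL	Cook County
alias	bk	NY	Kings County
alias	socal	CA
alias	bay area	CA
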