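# Ending the HIV Epidemic (EHE) Phase I priority jurisdictions:
# 48 counties + the District of Columbia, plus 7 states with substantial
# rural HIV burden. San Juan Municipio (PR) is part of the federal list
# but is omitted here because the gazetteer covers the 50 states + DC.
# Editable fixture.
kind,name,state
county,Maricopa County,AZ
county,Alameda County,CA
county,Los Angeles County,CA
county,Orange County,CA
county,Riverside County,CA
county,Sacramento County,CA
county,San Bernardino County,CA
county,San Diego County,CA
county,San Francisco County,CA
county,District of Columbia,DC
county,Broward County,FL
county,Duval County,FL
county,Hillsborough County,FL
county,Miami-Dade County,FL
county,Orange County,FL
county,Palm Beach County,FL
county,Pinellas County,FL
county,Cobb County,GA
county,DeKalb County,GA
county,Fulton County,GA
county,Gwinnett County,GA
county,Cook County,IL
county,Marion County,IN
county,East Baton Rouge Parish,LA
county,Orleans Parish,LA
county,Baltimore City,MD
county,Montgomery County,MD
county,Prince George's County,MD
county,Suffolk County,MA
county,Wayne County,MI
county,Clark County,NV
county,Essex County,NJ
county,Hudson County,NJ
county,Bernalillo County,NM
county,Bronx County,NY
county,Kings County,NY
county,New York County,NY
county,Queens County,NY
county,Mecklenburg County,NC
county,Cuyahoga County,OH
county,Franklin County,OH
county,Hamilton County,OH
county,Philadelphia County,PA
county,Shelby County,TN
county,Bexar County,TX
county,Dallas County,TX
county,Harris County,TX
county,Tarrant County,TX
county,Travis County,TX
county,King County,WA
county,Milwaukee County,WI
state,Alabama,AL
state,Arkansas,AR
state,Kentucky,KY
state,Mississippi,MS
state,Missouri,MO
state,Oklahoma,OK
state,South Carolina,SC
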